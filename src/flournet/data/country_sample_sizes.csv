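country,n
Argentina,6724
Australia,3844
Brazil,13204
Egypt,4729
Germany,9506
Hong Kong,3012
India,12765
Indonesia,6992
Israel,3669
Japan,20543
Kenya,11389
Mexico,5776
Nigeria,6827
Philippines,5292
Poland,10389
South Africa,2651
Spain,6290
Tanzania,9075
Turkiye,1473
United Kingdom,5368
United States,38312
Sweden,15068
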