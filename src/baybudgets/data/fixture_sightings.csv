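individual_id,date,bay
D1,2011-01-01,Makako
D1,2011-01-03,Makako
D1,2011-01-05,Kealakekua
D2,2011-01-01,Makako
D3,2011-01-02,Kealakekua
D3,2011-01-04,Kauhako
D4,2011-01-02,Makako
D4,2011-01-04,Makako
D4,2011-01-06,Makako
D5,2011-01-03,Honaunau
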