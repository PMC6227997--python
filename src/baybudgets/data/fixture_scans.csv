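follow_id,timestamp,platform,location,activity,n_boats,n_kayaks,n_swimmers
F01,2011-01-02T09:00,BOAT,Makako,REST,0,0,0
F01,2011-01-02T09:10,BOAT,Makako,REST,0,0,0
F01,2011-01-02T09:20,BOAT,Makako,REST,1,0,0
F01,2011-01-02T09:30,BOAT,Makako,SOCIAL,0,1,1
F01,2011-01-02T09:40,BOAT,Makako,TRAVEL,0,0,2
F01,2011-01-02T09:50,BOAT,Makako,REST,0,0,0
F02,2011-01-03T10:00,LAND,Kealakekua,SOCIAL,0,1,0
F02,2011-01-03T10:10,LAND,Kealakekua,REST,0,1,1
F02,2011-01-03T10:20,LAND,Kealakekua,REST,0,2,0
F02,2011-01-03T10:30,LAND,Kealakekua,REST,0,1,2
F03,2011-01-04T08:00,BOAT,OUTSIDE,TRAVEL,1,0,0
F03,2011-01-04T08:10,BOAT,OUTSIDE,TRAVEL,0,0,0
F03,2011-01-04T08:20,BOAT,OUTSIDE,SOCIAL,0,0,0
F03,2011-01-04T08:30,BOAT,OUTSIDE,REST,0,0,1
F03,2011-01-04T08:40,BOAT,OUTSIDE,TRAVEL,2,0,1
F04,2011-01-06T11:00,BOAT,Honaunau,REST,0,0,0
F04,2011-01-06T11:10,BOAT,Honaunau,REST,0,0,2
F04,2011-01-06T11:20,BOAT,Honaunau,SOCIAL,1,0,1
F05,2011-01-07T13:00,LAND,Kauhako,REST,0,1,0
F05,2011-01-07T13:10,LAND,Kauhako,TRAVEL,0,1,1
F05,2011-01-07T13:20,LAND,Kauhako,REST,0,0,0
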