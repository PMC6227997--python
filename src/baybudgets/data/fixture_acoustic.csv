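bay,date,status
Makako,2011-01-01,PRESENT
Makako,2011-01-02,PRESENT
Makako,2011-01-03,PRESENT
Makako,2011-01-04,PRESENT
Makako,2011-01-05,ABSENT
Makako,2011-01-06,PRESENT
Makako,2011-01-07,PRESENT
Makako,2011-01-08,PRESENT
Makako,2011-01-09,PRESENT
Makako,2011-01-10,PRESENT
Makako,2011-01-11,PRESENT
Makako,2011-01-12,PRESENT
Kealakekua,2011-01-01,PRESENT
Kealakekua,2011-01-02,PRESENT
Kealakekua,2011-01-03,PRESENT
Kealakekua,2011-01-04,PRESENT
Kealakekua,2011-01-05,PRESENT
Kealakekua,2011-01-06,PRESENT
Kealakekua,2011-01-07,ABSENT
Kealakekua,2011-01-08,ABSENT
Kealakekua,2011-01-09,ABSENT
Kealakekua,2011-01-10,ABSENT
Honaunau,2011-01-01,ABSENT
Honaunau,2011-01-02,ABSENT
Honaunau,2011-01-03,PRESENT
Honaunau,2011-01-04,ABSENT
Honaunau,2011-01-05,ABSENT
Honaunau,2011-01-06,PRESENT
Honaunau,2011-01-07,ABSENT
Honaunau,2011-01-08,ABSENT
Honaunau,2011-01-09,PRESENT
Honaunau,2011-01-10,ABSENT
Honaunau,2011-01-11,ABSENT
Honaunau,2011-01-12,PRESENT
Kauhako,2011-01-01,PRESENT
Kauhako,2011-01-02,ABSENT
Kauhako,2011-01-03,PRESENT
Kauhako,2011-01-04,ABSENT
Kauhako,2011-01-05,PRESENT
Kauhako,2011-01-06,ABSENT
Kauhako,2011-01-07,PRESENT
Kauhako,2011-01-08,ABSENT
Kauhako,2011-01-09,PRESENT
Kauhako,2011-01-10,ABSENT
Kauhako,2011-01-11,PRESENT
Kauhako,2011-01-12,ABSENT
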