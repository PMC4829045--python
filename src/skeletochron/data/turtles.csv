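id,date_tagged,scl_tagging_cm,date_otc,date_stranded,scl_recovery_cm,fibropapilloma
CM-1,1997-04-23,55.1,1997-04-23,1999-02-08,58.5,false
CM-4,1998-12-21,69.4,1998-12-21,1999-12-10,69.6,true
CM-6,1999-10-05,55.9,,2000-05-09,56.3,false
CM-8,2000-04-24,70.6,,2001-02-20,70,false
CM-9,2000-04-14,44.7,,2001-04-23,44.5,true
CM-10,2000-04-25,83.8,,2001-12-11,85.5,true
CM-11,1997-07-08,54.8,1997-07-08,2002-03-28,57.2,true
CM-12,1998-05-12,57.4,1998-05-12,2002-10-17,60.2,true
CM-13,1994-06-17,45.5,1994-06-17,2003-10-19,69.5,false
CM-14,2000-05-16,51,2000-05-16,2004-07-14,53.7,true
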