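specimen_id,population_code,species,clade,group,unbleached,IN,TI,HE,DO,SP,SO,HO,SH,SC,CO,RO,GR,CD,RI,RD
CD01/1,CD01,M. tuberculata,1,invasive,1,4,5,0,0,na,na,na,1,na,1,2,2,0,3,1
CD01-A,CD01,M. tuberculata,1,invasive,0,2,2,0,2,2,3,1,2,2,1,2,2,0,1,1
CD01-B,CD01,M. tuberculata,1,invasive,0,2,4,0,2,1,2,1,1,na,1,2,2,0,3,1
CD05-A,CD05,M. tuberculata,1,invasive,0,1,4,0,1,1,2,1,1,na,1,2,2,0,3,1
CD05-B,CD05,M. tuberculata,1,invasive,0,2,1,0,2,1,2,1,1,na,1,2,1,0,0,na
CD06-A,CD06,M. tuberculata,1,invasive,0,1,4,0,1,2,"1, 2",1,1,na,1,2,2,0,3,1
CD06-B,CD06,M. tuberculata,1,invasive,0,2,1,0,1,2,"1, 2",1,1,na,1,2,1,0,0,na
CD05-06 F1,CD05-06,M. tuberculata,1,invasive,0,"2, 3",1,0,2,2,2,1,2,2,1,2,2,0,0,na
CD07-A,CD07,M. tuberculata,1,invasive,0,2,2,0,1,2,2,2,2,1,1,3,1,0,3,1
CD07-B,CD07,M. tuberculata,1,invasive,0,"2, 3",1,0,1,1,2,1,1,na,1,3,1,0,0,na
CD09-A,CD09,M. tuberculata,1,invasive,0,3,1,0,1,2,1,1,1,na,1,2,1,0,3,1
CD09-B,CD09,M. tuberculata,1,invasive,0,2,1,0,1,2,2,1,2,2,1,2,1,0,1,1
CD10/1-4,CD10,M. tuberculata,1,invasive,1,4,5,0,0,na,na,na,1,na,1,2,3,0,3,"2, 1"
CD10-A,CD10,M. tuberculata,1,invasive,0,2,1,0,0,na,na,na,2,2,1,3,2,0,3,2
CD10-B,CD10,M. tuberculata,1,invasive,0,2,4,0,1,2,1,1,1,na,1,3,2,0,3,2
CD11/1-4,CD11,M. tuberculata,1,invasive,1,4,5,0,0,na,na,na,1,na,1,2,2,0,0,na
LMI_1,LMI,M. tuberculata,1,invasive,0,2,1,0,2,2,2,1,2,2,1,2,2,0,0,na
LMI_2,LMI,M. tuberculata,1,invasive,0,2,2,0,2,2,2,1,2,2,1,2,2,0,0,na
LMI_3,LMI,M. tuberculata,1,invasive,0,3,2,0,2,2,3,1,3,3,1,3,2,0,0,na
LMI_4,LMI,M. tuberculata,1,invasive,0,2,1,0,2,2,3,1,3,3,1,2,2,0,0,na
MW11/1,MW11,M. tuberculata,1,native,0,3,2,0,2,2,2,1,1,na,1,2,2,0,1,1
MW12/1,MW12,M. tuberculata,1,native,0,3,2,0,2,2,2,1,2,2,1,2,2,0,1,1
CD02/1,CD02,M. cf. liebrechtsi,2,native,0,3,1,0,2,2,2,2,1,na,2,2,2,2,2,1
CD02/2,CD02,M. cf. liebrechtsi,2,native,0,3,1,0,2,2,2,2,1,na,2,2,2,2,2,2
CD02/3,CD02,M. cf. nsendweensis,2,native,0,2,1,0,0,na,na,na,1,na,3,1,2,0,2,2
CD03/1,CD03,M. cf. liebrechtsi,2,native,0,2,1,0,1,2,2,2,1,na,2,2,"2, 3",0,1,1
CD03-A,CD03,M. cf. liebrechtsi,2,native,0,2,1,0,2,2,1,2,1,na,2,2,"2, 3",2,2,2
CD03-B,CD03,M. cf. liebrechtsi,2,native,0,3,1,0,2,2,2,2,1,na,2,"1, 2",2,2,2,1
CD04/1,CD04,M. cf. liebrechtsi,2,native,0,2,1,0,2,2,2,2,1,na,2,2,2,2,2,2
CD04-A,CD04,M. cf. liebrechtsi,2,native,0,2,1,0,1,2,1,2,1,na,2,2,2,2,2,2
CD04-B,CD04,M. cf. liebrechtsi,2,native,0,2,1,0,2,2,2,"2, 3",1,na,2,2,2,2,2,2
CD08-A,CD08,M. cf. liebrechtsi,2,native,0,1,4,0,1,3,2,2,1,na,1,2,1,3,2,2
CD08-B,CD08,M. cf. liebrechtsi,2,native,0,1,4,0,1,2,2,2,1,na,1,2,"1, 2",3,2,"1, 2"
BI01/1,BI01,M. tuberculata,2,invasive,0,"2, 3",1,1,1,1,2,3,2,2,1,2,1,0,3,1
BI01/2,BI01,M. tuberculata,2,invasive,0,2,2,1,1,1,2,3,2,3,1,2,1,0,3,1
BI01/3,BI01,M. tuberculata,2,invasive,0,3,2,1,1,1,2,3,2,3,1,2,1,0,3,1
BI01/4,BI01,M. tuberculata,2,invasive,0,2,2,1,1,1,2,3,2,2,1,2,1,0,3,1
MW10/3,MW10,M. tuberculata,2,native,0,4,5,0,0,na,na,na,1,na,3,3,3,0,2,3
MW13/2,MW13,M. tuberculata,2,native,0,3,1,0,2,2,1,2,1,na,2,3,3,0,3,3
MW13-A,MW13,M. tuberculata,2,native,0,2,1,0,0,na,na,na,1,na,2,2,3,0,3,3
RW01/1,RW01,M. tuberculata,2,native,0,1,1,0,0,na,na,na,1,na,2,3,3,0,3,3
RW01/2,RW01,M. tuberculata,2,native,0,2,1,1,2,2,2,3,1,na,2,2,2,0,1,1
UG01/1,UG01,M. tuberculata,2,native,0,"2, 3",1,0,2,2,2,1,3,2,1,3,3,0,2,3
UG02/1,UG02,M. tuberculata,2,native,0,3,1,0,1,2,1,1,1,na,1,2,2,0,3,1
UG03/1,UG03,M. tuberculata,2,native,0,3,1,1,2,2,1,2,2,2,1,"2, 3",2,0,1,1
CD12/1,CD12,M. tuberculata,2,native,0,3,1,0,2,1,3,1,1,na,1,3,2,0,3,1
CD13/1,CD13,M. tuberculata,2,native,0,3,1,1,1,2,2,2,1,na,1,2,1,0,3,1
CD14/1,CD14,M. tuberculata,2,native,0,1,1,0,1,2,2,2,1,na,2,2,1,0,3,1
CD14/2,CD14,M. tuberculata,2,native,0,2,1,0,2,2,2,2,2,1,1,3,2,0,3,2
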