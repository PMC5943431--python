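drug,site,subgroup_label,subgroup_fraction,survival_gain_years,eligible_na,eligible_ww,site_deaths_na,site_deaths_ww,discovery_date,approval_date,duration_override_years,reference_tags
Erlotinib,NSCLC,NSCLC,0.85,0.17,152794,1351418,179758,1589904,1996-05,2004-11,8.5,
Bevacizumab,NSCLC,nonsquamous,0.60,0.17,95559,953941,179758,1589904,1995-05,2006-10,11.4,
Nivolumab,NSCLC,squamous,0.25,0.27,44941,397474,179758,1589904,2002,2015-03,13,
Eribulin,Breast,all,1.0,0.21,45529,521900,45529,521900,2001-04,2010-11,9.6,
Trastuzumab,Breast,HER2-positive,0.20,0.40,9106,104371,45529,521900,1990,1998-09,8,
Trastuzumab emtansine,Breast,HER2-positive,0.20,0.48,9106,104371,45529,521900,2004-10,2013-02,8.3,
Pertuzumab,Breast,HER2-positive,0.20,1.31,9106,104371,45529,521900,2000-06,2012-06,12,
Bevacizumab,Colorectal,all,1.0,0.39,59100,693900,59100,693900,1995-05,2004-02,8.8,
Oxaliplatin,Colorectal,all,1.0,0.38,59100,693900,59100,693900,1980-10,2004-01,23.3,
Regorafenib,Colorectal,all,1.0,0.12,59100,693900,59100,693900,2000-01,2012-02,12.1,
Cetuximab,Colorectal,EGFR-positive,0.97,0.13,57823,673086,59100,693900,1988-09,2004-02,15.4,
Trastuzumab,Gastric,HER2-positive,0.21,0.23,2748,151852,,,1990,2010-10,20,
Cetuximab,Head and neck,squamous,0.90,0.23,8926,199800,,,1988-09,2011-11,23.2,
Cabazitaxel,Prostate,all,1.0,0.20,33480,307500,33480,307500,1993-11,2010-06,16.6,
Enzalutamide,Prostate,all,1.0,0.40,33480,307500,33480,307500,2006-05,2012-08,6.3,
Abiraterone,Prostate,all,1.0,0.38,33480,307500,33480,307500,1994-09,2011-04,16.6,
Sipuleucel-T,Prostate,all,1.0,0.36,33480,307500,33480,307500,1998-09,2010-04,11.6,
Temsirolimus,Renal,all,1.0,0.30,15610,116000,15610,116000,1994-04,2007-05,13.1,
Sunitinib,Renal,all,1.0,0.38,15610,116000,15610,116000,1999-12,2006-01,6.1,
Sorafenib,Renal,all,1.0,0.29,15610,116000,15610,116000,1999-02,2005-12,6.8,
Ipilimumab,Melanoma,all,1.0,0.31,10760,46000,10760,46000,1997,2011-03,14,
Vemurafenib,Melanoma,BRAF-mutant,0.50,0.33,5380,23000,10760,46000,2004-12,2011-08,6.8,
Nivolumab,Melanoma,BRAF-wild-type,0.50,0.42,5380,23000,10760,46000,2002,2014-12,12,
Pomalidomide,Myeloma,all,1.0,0.39,12400,72000,12400,72000,1996-07,2013-02,16.6,
Bortezomib,Myeloma,all,1.0,1.11,12490,72000,12490,72000,1995-05,2008-06,13.1,
Sorafenib,Hepatocellular,all,1.0,0.23,24050,745500,24050,745500,1999-02,2007-11,8.8,
Bevacizumab,Cervix,all,1.0,0.31,4400,265700,4400,265700,1995-05,2014-08,19.3,
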