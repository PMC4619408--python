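name,life_form,thermal_class,leaf_class,phenology,tc_min,tc_max,gdd5_min,twtc_min
tropical broadleaf evergreen,woody,tropical,broadleaf,evergreen,15.5,,,
tropical broadleaf raingreen,woody,tropical,broadleaf,raingreen,15.5,,,
temperate needleleaf evergreen,woody,temperate,needleleaf,evergreen,-19.0,,900,
temperate broadleaf evergreen,woody,temperate,broadleaf,evergreen,-1.0,18.8,1200,
temperate broadleaf summergreen,woody,temperate,broadleaf,summergreen,-17.0,15.5,1200,
boreal needleleaf evergreen,woody,boreal,needleleaf,evergreen,-32.5,0.0,600,
boreal needleleaf summergreen,woody,boreal,needleleaf,summergreen,,-2.0,350,43
boreal broadleaf summergreen,woody,boreal,broadleaf,summergreen,,-2.0,350,
temperate herbaceous,herbaceous,temperate,herb,,,15.5,,
tropical herbaceous,herbaceous,tropical,herb,,,,,
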