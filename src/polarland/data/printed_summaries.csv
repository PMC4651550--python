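kind,label,k1,n1,k2,n2,mean1,sd1,mean2,sd2
logistic,land_use_gt7,16,80,14,36,,,,
logistic,land_use_gt21,10,80,13,36,,,,
logistic,land_use_gt7_alaska_capture,3,23,14,36,,,,
logistic,land_use_gt21_alaska_capture,0,23,13,36,,,,
logistic,pct_locations_lt5,40,75,16,35,,,,
anova,days_on_land_gt7,,16,,14,32.7,21.1,62.6,20.2
anova,days_on_land_gt21,,10,,13,44.7,17.5,65.9,16.7
anova,days_on_land_alaska_capture,,3,,14,14.7,4.0,62.6,20.2
anova,arrival_doy,,16,,14,261.4,22.7,241.2,20.2
anova,departure_doy_nondenning,,12,,7,287.4,19.3,309.7,6.7
anova,post_denning_departure_doy,,13,,13,98.5,15.8,87.8,26.7
anova,pct_locations_on_land,,75,,35,11.1,15.6,22.9,25.7
anova,shelf_ice_fraction_aug_oct,,10,,6,29.4,9.1,11.1,3.7
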