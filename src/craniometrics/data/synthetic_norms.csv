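category,mean,sd,p10,p25,p50,p75,p90
physical_wellbeing,72.0,15.0,52.0,62.0,73.0,83.0,91.0
psychological_wellbeing,78.0,13.0,61.0,70.0,79.0,88.0,94.0
moods_emotions,76.0,14.0,58.0,67.0,77.0,86.0,93.0
self_perception,70.0,15.0,50.0,60.0,71.0,81.0,89.0
autonomy,71.0,16.0,50.0,60.0,72.0,83.0,91.0
parent_relations_home,77.0,14.0,59.0,68.0,78.0,87.0,94.0
financial_resources,69.0,21.0,41.0,54.0,71.0,86.0,96.0
social_support_peers,74.0,15.0,54.0,64.0,75.0,85.0,92.0
school_environment,68.0,16.0,47.0,57.0,69.0,80.0,88.0
social_acceptance,82.0,16.0,60.0,72.0,85.0,94.0,99.0
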