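country,year,population,r4h_budget,total_health_budget,r4h_policy,r4h_legislation,r4h_strategic_plan,ethics_committee,research_focal_point,prioritized_agenda,research_programme,staff_per_100k,internet_connectivity,research_council,universities_per_million,ngo_r4h,research_forum,knowledge_translation,pubs_per_100k,budget_line
Mauritius,2020,1267000,38395000.0,11700000000.0,0,1,0,1,1,0,1,40,1,1,4,1,0,1,89,1
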