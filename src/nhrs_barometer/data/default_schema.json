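{
  "name": "African NHRS barometer (Mauritius 2020 goalposts)",
  "version": "1.0",
  "functions": [
    {
      "id": "leadership_governance",
      "name": "Leadership and governance of R4H",
      "indicator_ids": [
        "r4h_policy",
        "r4h_legislation",
        "r4h_strategic_plan",
        "ethics_committee",
        "research_focal_point",
        "prioritized_agenda"
      ]
    },
    {
      "id": "developing_resources",
      "name": "Developing and sustaining resources for R4H",
      "indicator_ids": [
        "research_programme",
        "staff_per_100k",
        "internet_connectivity",
        "research_council",
        "universities_per_million",
        "ngo_r4h"
      ]
    },
    {
      "id": "producing_utilizing",
      "name": "Producing and utilizing R4H",
      "indicator_ids": [
        "research_forum",
        "knowledge_translation",
        "pubs_per_100k"
      ]
    },
    {
      "id": "financing",
      "name": "Financing R4H",
      "indicator_ids": [
        "budget_line",
        "budget_share_pct"
      ]
    }
  ],
  "indicators": [
    {
      "id": "r4h_policy",
      "label": "Existence of a national R4H policy",
      "function_id": "leadership_governance",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 1
    },
    {
      "id": "r4h_legislation",
      "label": "Existence of a legislation/law relating to R4H",
      "function_id": "leadership_governance",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 2
    },
    {
      "id": "r4h_strategic_plan",
      "label": "Existence of a strategic R4H plan",
      "function_id": "leadership_governance",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 3
    },
    {
      "id": "ethics_committee",
      "label": "Existence of a national research ethics committee",
      "function_id": "leadership_governance",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 4
    },
    {
      "id": "research_focal_point",
      "label": "Existence of a national health research focal point/unit",
      "function_id": "leadership_governance",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 5
    },
    {
      "id": "prioritized_agenda",
      "label": "Existence of a national R4H prioritized agenda",
      "function_id": "leadership_governance",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 6
    },
    {
      "id": "research_programme",
      "label": "Existence of a health research programme/directorate at the health ministry",
      "function_id": "developing_resources",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 7
    },
    {
      "id": "staff_per_100k",
      "label": "Technical and support staff in the R4H programme per 100,000 population",
      "function_id": "developing_resources",
      "kind": "continuous",
      "scaling": "per_100k_population",
      "goalpost_min": 0.0,
      "goalpost_max": 100.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 8
    },
    {
      "id": "internet_connectivity",
      "label": "Whether the R4H programme has internet connectivity",
      "function_id": "developing_resources",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 9
    },
    {
      "id": "research_council",
      "label": "Presence of a national research and innovation council",
      "function_id": "developing_resources",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 10
    },
    {
      "id": "universities_per_million",
      "label": "Universities and colleges conducting R4H per million population",
      "function_id": "developing_resources",
      "kind": "continuous",
      "scaling": "per_million_population",
      "goalpost_min": 0.0,
      "goalpost_max": 5.39,
      "goalpost_source": "cohort_max",
      "benchmark_note": "Cabo Verde, African Region 2018 survey maximum",
      "order": 11
    },
    {
      "id": "ngo_r4h",
      "label": "Existence of non-governmental organization(s) undertaking R4H",
      "function_id": "developing_resources",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 12
    },
    {
      "id": "research_forum",
      "label": "Existence of a national health research management forum",
      "function_id": "producing_utilizing",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 13
    },
    {
      "id": "knowledge_translation",
      "label": "Existence of a knowledge translation platform",
      "function_id": "producing_utilizing",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 14
    },
    {
      "id": "pubs_per_100k",
      "label": "Peer-reviewed R4H publications in the 12-month window per 100,000 population",
      "function_id": "producing_utilizing",
      "kind": "continuous",
      "scaling": "per_100k_population",
      "goalpost_min": 0.0,
      "goalpost_max": 12.514,
      "goalpost_source": "cohort_max",
      "benchmark_note": "South Africa, African Region maximum",
      "order": 15
    },
    {
      "id": "budget_line",
      "label": "Presence of a funded R4H budget line within the government budget",
      "function_id": "financing",
      "kind": "binary",
      "scaling": "none",
      "goalpost_min": 0.0,
      "goalpost_max": 1.0,
      "goalpost_source": "fixed",
      "benchmark_note": null,
      "order": 16
    },
    {
      "id": "budget_share_pct",
      "label": "Percentage of the health ministry budget allocated to R4H",
      "function_id": "financing",
      "kind": "continuous",
      "scaling": "percent_of_total_budget",
      "goalpost_min": 0.0,
      "goalpost_max": 2.0,
      "goalpost_source": "policy_target",
      "benchmark_note": "Regional target: at least 2% of the health budget on R4H",
      "order": 17
    }
  ]
}
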