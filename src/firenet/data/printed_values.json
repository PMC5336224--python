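{
  "historical": {
    "ignitions_total": 11618,
    "record_years": 18,
    "natural_area_per_yr_ha": 7877,
    "human_area_per_yr_ha": 7184,
    "natural_ignitions": 6379,
    "human_ignitions": 5239,
    "ignitions_per_yr": 645,
    "natural_mean_size_ha": 22
  },
  "networks": [
    {"scale": "community", "nodes": 66, "edges": 862, "density": 0.2},
    {"scale": "tenure", "nodes": 12, "edges": 129, "density": 0.977}
  ],
  "results": {
    "community_incoming_fraction": 0.67,
    "mean_incoming_fraction": 0.57,
    "min_incoming_fraction": 0.14,
    "max_incoming_fraction": 0.86,
    "private_incoming_fraction": 0.69,
    "cross_boundary_share": 0.39,
    "community_share_of_transmitted": 0.21,
    "community_human_total_ha": 1400,
    "national_forest_total_ha": 8554,
    "human_grand_total_ha": 11200,
    "natural_grand_total_ha": 10460
  }
}
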