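{
  "items": [
    {"item_id": "trust_honest", "dimension": "cognitive", "subdomain": "trust",
     "text": "Most people in your village are honest and can be trusted.",
     "calib_mean": 3.24, "calib_sd": 0.85},
    {"item_id": "recip_welfare", "dimension": "cognitive", "subdomain": "reciprocity",
     "text": "Most people in your village are concerned for their welfare.",
     "calib_mean": 2.36, "calib_sd": 0.96},
    {"item_id": "recip_help", "dimension": "cognitive", "subdomain": "reciprocity",
     "text": "You get help from friends when needed (there is always someone in this village to help you).",
     "calib_mean": 3.37, "calib_sd": 0.87},
    {"item_id": "recip_advantage", "dimension": "cognitive", "subdomain": "reciprocity",
     "text": "Most people in your village would try to take advantage of you if you were not alert.",
     "calib_mean": 2.67, "calib_sd": 0.89, "negative_keyed": true},
    {"item_id": "recip_goat", "dimension": "cognitive", "subdomain": "reciprocity",
     "text": "If you lose a goat, someone in your village will help you find it or return it to you if she or he finds it.",
     "calib_mean": 3.40, "calib_sd": 0.77},
    {"item_id": "norm_attention", "dimension": "cognitive", "subdomain": "social_norms",
     "text": "You do pay attention to what others think or say about you.",
     "calib_mean": 2.54, "calib_sd": 0.97},
    {"item_id": "norm_status", "dimension": "cognitive", "subdomain": "social_norms",
     "text": "Most of the people in your village worry about their social status.",
     "calib_mean": 3.14, "calib_sd": 0.95},
    {"item_id": "norm_wrong", "dimension": "cognitive", "subdomain": "social_norms",
     "text": "You do not do anything your partner or villagers would say is wrong.",
     "calib_mean": 3.18, "calib_sd": 1.11},
    {"item_id": "norm_accepted", "dimension": "cognitive", "subdomain": "social_norms",
     "text": "You feel accepted as a member of your village.",
     "calib_mean": 3.52, "calib_sd": 0.59},
    {"item_id": "part_projects", "dimension": "bonding", "subdomain": "participation",
     "text": "In the past 12 months, how often did you join in village projects (e.g., tree planting)?",
     "calib_mean": 2.98, "calib_sd": 0.88},
    {"item_id": "part_volunteer", "dimension": "bonding", "subdomain": "participation",
     "text": "In the past 12 months, how often did you take part in voluntary activities as a volunteer?",
     "calib_mean": 3.99, "calib_sd": 0.21},
    {"item_id": "part_prayer", "dimension": "bonding", "subdomain": "participation",
     "text": "Frequency of prayer per day with your family, neighbors, or other members of your village.",
     "calib_mean": 3.64, "calib_sd": 0.89},
    {"item_id": "memb_org", "dimension": "bonding", "subdomain": "membership",
     "text": "Average membership in an organization.",
     "calib_mean": 2.54, "calib_sd": 0.50}
  ]
}
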