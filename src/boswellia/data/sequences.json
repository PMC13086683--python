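{
  "sequences": [
    ["shuffling", "shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling"],
    ["shuffling", "shuffling", "voting_shuffling_reputation", "voting_shuffling_reputation", "voting_shuffling", "voting_shuffling"],
    ["shuffling", "shuffling", "voting_shuffling_reputation", "voting_shuffling_reputation", "voting_shuffling", "voting_shuffling"],
    ["shuffling", "shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling"],
    ["shuffling", "shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling_reputation", "voting_shuffling_reputation"],
    ["shuffling", "shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling"],
    ["shuffling", "shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling", "voting_shuffling"]
  ]
}
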