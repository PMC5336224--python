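tenure,area_100ha,total_pct,total_fire,nontf_human,tfin_human,tfout_human,nontf_natural,tfin_natural,tfout_natural
BLM,2050,6,1377,233,406,410,283,456,465
Community,4338,13,2580,496,905,826,352,828,698
NF-M,9350,29,4559,1139,679,764,1791,950,1094
NF-P,9280,28,3996,1056,709,777,1429,801,1085
NPS,390,1,72,4,9,2,37,23,24
Native,2460,8,6706,3738,525,487,2000,443,351
ODF,180,1,66,5,36,21,4,21,16
OtherFED,290,1,423,59,138,124,53,172,93
Private,1450,4,829,70,337,304,50,371,223
PrivateIndustrial,2140,7,882,299,269,314,106,208,175
USFWS,300,1,129,25,37,34,19,47,57
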