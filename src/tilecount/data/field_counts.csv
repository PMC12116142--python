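plant_id,side_a,side_b,raw_total,reference,corrected
1,54,96,150,184.50,202.46
2,75,147,222,165.50,137.14
3,47,152,199,285.75,309.36
4,76,183,259,518.50,499.39
5,163,0,163,339.00,331.13
6,102,157,336,647.75,651.82
7,89,85,175,242.25,251.95
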