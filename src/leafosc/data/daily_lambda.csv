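order,date,lam_co,lam_vc,lam_vj
1,2021-04-29,520.89,525.86,
2,2021-06-29,"1,643.41","1,667.70","1,321.57"
3,2021-07-02,"2,138.93","1,780.99","3,248.67"
4,2021-07-03,"2,570.25","2,240.79","2,802.25"
5,2021-07-20,"2,922.37",,"2,922.37"
6,2021-07-31,"1,215.57","1,191.83","1,954.64"
7,2021-08-02,"1,458.09","1,458.09",
8,2021-08-06,"1,810.29",,"1,840.31"
9,2021-09-15,"1,625.71","1,599.26","3,208.17"
10,2022-04-29,426.87,360.87,594.94
11,2022-06-24,"2,029.29","1,511.00","2,888.72"
12,2022-07-06,"2,000.97","1,696.35","3,033.92"
13,2022-07-07,"3,135.39","3,134.98",
14,2022-07-21,"1,769.87","1,228.22","2,072.09"
15,2022-07-22,"2,443.56","2,032.39","2,958.37"
16,2022-08-09,"2,448.98","2,378.56","2,548.55"
17,2022-10-01,"2,689.75",,"2,691.51"
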