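subject,wright_large_1,wright_large_2,wright_mini_1,wright_mini_2
1,494,490,512,525
2,395,397,430,415
3,516,512,520,508
4,434,401,428,444
5,476,470,500,500
6,557,611,600,625
7,413,415,364,460
8,442,431,380,390
9,650,638,658,642
10,433,429,445,432
11,417,420,432,420
12,656,633,626,605
13,267,275,260,227
14,478,492,477,467
15,178,165,259,268
16,423,372,350,370
17,427,421,451,443
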