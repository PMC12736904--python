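{
 "series": [
  156.2,
  161.28,
  160.55,
  161.87,
  163.43,
  175.29,
  169.43,
  161.67,
  157.32,
  162.65
 ],
 "edges": [
  [
   0,
   1
  ],
  [
   1,
   2
  ],
  [
   1,
   3
  ],
  [
   1,
   4
  ],
  [
   1,
   5
  ],
  [
   2,
   3
  ],
  [
   2,
   4
  ],
  [
   2,
   5
  ],
  [
   3,
   4
  ],
  [
   3,
   5
  ],
  [
   4,
   5
  ],
  [
   5,
   6
  ],
  [
   5,
   9
  ],
  [
   6,
   7
  ],
  [
   6,
   8
  ],
  [
   6,
   9
  ],
  [
   7,
   8
  ],
  [
   7,
   9
  ],
  [
   8,
   9
  ]
 ],
 "weights": [
  3.115286212139982,
  0.7911155514429806,
  0.5023726699045377,
  1.2993648575661212,
  7.3385370445031075,
  1.1444928675415234,
  1.7827617325496952,
  7.744002189884105,
  1.2801511726190387,
  7.14457078015354,
  6.527335652032539,
  3.5103551974619047,
  6.647862352389,
  4.468527331630502,
  6.4864241988297335,
  3.720843076222021,
  2.743967421821248,
  0.7311231306422554,
  3.2420670201719055
 ],
 "thetas": [
  1.376431060699879,
  -0.6305777572149281,
  0.28686334952267994,
  0.6218242878305911,
  1.2926852225155603,
  0.9224643377076335,
  0.9638086627484879,
  1.3700109494205768,
  1.000755863095187,
  1.4228539007677277,
  1.4866782601627322,
  -1.4017759873095605,
  -1.264311761945034,
  -1.4426366581524588,
  -1.4071209941486333,
  -1.1542153811101015,
  -1.3448371091062556,
  0.4556156532112318,
  1.3853351008594965
 ],
 "features": {
  "edge_count": 19.0,
  "edge_weight_kurtosis": -1.3939477911132165,
  "edge_weight_mean": 3.695850550500302,
  "edge_weight_skewness": 0.31057891542697363,
  "edge_weight_variance": 6.1749445382382415,
  "gini_index": 0.3791309683490327,
  "global_efficiency": 0.28317139868254243,
  "modularity": 0.32507242647082535,
  "weighted_average_degree": 14.044232091901147,
  "average_degree": 3.8,
  "average_betweenness": 0.11388888888888887,
  "average_node_strength": 14.044232091901147,
  "average_path_length": 8.974106375164203,
  "waii": 0.37934351943505945,
  "cbefi": 2.879002192982456
 }
}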