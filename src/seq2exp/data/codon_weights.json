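{
 "AAA": 1.0,
 "AAC": 1.0,
 "AAG": 0.3065,
 "AAT": 0.8157,
 "ACA": 0.3034,
 "ACC": 1.0,
 "ACG": 0.6154,
 "ACT": 0.3846,
 "AGA": 0.0955,
 "AGC": 1.0,
 "AGG": 0.0545,
 "AGT": 0.5466,
 "ATA": 0.1452,
 "ATC": 0.8284,
 "ATG": 1.0,
 "ATT": 1.0,
 "CAA": 0.5312,
 "CAC": 0.7519,
 "CAG": 1.0,
 "CAT": 1.0,
 "CCA": 0.3621,
 "CCC": 0.2371,
 "CCG": 1.0,
 "CCT": 0.3017,
 "CGA": 0.1636,
 "CGC": 1.0,
 "CGG": 0.2455,
 "CGT": 0.95,
 "CTA": 0.0741,
 "CTC": 0.2091,
 "CTG": 1.0,
 "CTT": 0.2091,
 "GAA": 1.0,
 "GAC": 0.595,
 "GAG": 0.4518,
 "GAT": 1.0,
 "GCA": 0.5982,
 "GCC": 0.7589,
 "GCG": 1.0,
 "GCT": 0.4554,
 "GGA": 0.2703,
 "GGC": 1.0,
 "GGG": 0.375,
 "GGT": 0.8345,
 "GTA": 0.4129,
 "GTC": 0.5795,
 "GTG": 1.0,
 "GTT": 0.6932,
 "TAC": 0.7531,
 "TAT": 1.0,
 "TCA": 0.4472,
 "TCC": 0.5342,
 "TCG": 0.5528,
 "TCT": 0.528,
 "TGC": 1.0,
 "TGG": 1.0,
 "TGT": 0.8125,
 "TTA": 0.2643,
 "TTC": 0.7477,
 "TTG": 0.2605,
 "TTT": 1.0
}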