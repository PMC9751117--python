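"""Encode DNA sequences under all six encodings and check their dimensions.

Each encoding trades resolution against dimensionality: global biophysical
properties (8 features), overlapping k-mers (counts or ordinal ranks), and
base-resolution one-hot (binary or ordinal), plus the mixed concatenation.
"""

from seq2exp.encoders import ENCODING_NAMES, encode
from seq2exp.synthetic import LibraryConfig, build_library

library = build_library(config=LibraryConfig(
    n_series=1, variants_per_series=50, length=96, master_seed=1))
seqs = [r.sequence for r in library.records]

print(f"{len(seqs)} sequences of length 96, k = 4 where applicable\n")
print("encoding        n_rows  n_cols")
for name in ENCODING_NAMES:
    m = encode(name, seqs, k=4)
    print(f"{name:<15} {m.n_rows:>6}  {m.n_cols:>6}")
print()
print("binary one-hot of a 96-nt sequence flattens to 4 x 96 = 384 features;")
print("mixed appends the 8 min-max-normalized biophysical properties (392).")
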