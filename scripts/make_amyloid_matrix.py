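"""One-off: freeze the amyloid position-weight matrix to package data.

Base per-residue propensity scale (beta-aggregation-style: aliphatic/aromatic
high, charged/proline low), modulated by a smooth positional envelope peaking
at the window centre, plus a small deterministic per-cell perturbation so no
two positions are identical.
"""
import math

AA = "ACDEFGHIKLMNPQRSTVWY"
base = {
    "I": 1.80, "F": 1.70, "V": 1.60, "L": 1.50, "Y": 1.40, "W": 1.30,
    "M": 0.90, "C": 0.70, "A": 0.60, "T": 0.20, "N": 0.05, "S": 0.00,
    "Q": -0.05, "G": -0.20, "H": -0.30, "R": -1.20, "D": -1.30, "E": -1.40,
    "K": -1.50, "P": -2.00,
}

rows = ["pos\t" + "\t".join(AA)]
for p in range(1, 22):
    env = 0.70 + 0.60 * math.exp(-((p - 11) ** 2) / 50.0)
    cells = []
    for j, aa in enumerate(AA):
        jitter = 0.05 * math.sin(0.7 * p + 1.3 * j)
        cells.append(f"{base[aa] * env + jitter:.4f}")
    rows.append(f"{p}\t" + "\t".join(cells))

with open("/root/pkg/src/prionscape/data/amyloid_matrix.tsv", "w") as fh:
    fh.write("\n".join(rows) + "\n")
print("written")
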