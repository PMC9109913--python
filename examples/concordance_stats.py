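"""Agreement statistics on a benign/pathogenic cross-tabulation.

The 2x2 table counts samples by their ddPCR label (rows) and aCGH label
(columns).  Cohen's kappa corrects the raw agreement for chance; the
verbal band follows the conventional 0.21/0.41/0.61/0.81 scale.
"""

import ddcnv

# ddPCR benign/aCGH benign = 71, ddPCR benign/aCGH pathogenic = 1,
# ddPCR pathogenic/aCGH benign = 7, both pathogenic = 19 (n = 98).
table = ddcnv.CrossTab2x2(a=71, b=1, c=7, d=19)

res = ddcnv.cohen_kappa(table)
print(f"n = {table.n}, observed agreement = {(table.a + table.d) / table.n:.3f}")
print(f"kappa = {res.kappa:.3f} ({res.band}), p = {res.p_value:.2e}")

exact = ddcnv.cohen_kappa(table, p_method="exact")
print(f"exact permutation p = {exact.p_value:.2e}")

# kappa ~ 0.774 means substantial chance-corrected agreement between the
# two methods on the pathogenic-vs-benign decision.
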