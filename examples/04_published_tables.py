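"""Recompute the published contingency and deviance tables from their counts.

The printed DC/NDC counts are inputs; every statistic is recomputed by
the package. Most rows reproduce to the printed precision; the known
divergent rows are printed alongside their recomputed values.
"""

import pandas as pd

import prolifsig as ps

rows = [
    ("moderately vs poorly/highly", 22, 44, 13, 66, 0.0017),
    ("moderately vs extremes, TPS<50%", 12, 27, 7, 51, 0.0063),
    ("moderately vs extremes, TPS>=50%", 10, 17, 6, 15, 0.4786),
    ("TPS>=1% vs TPS<1%", 21, 53, 14, 57, 0.1363),
    ("moderately vs highly, TPS<50%", 12, 27, 4, 29, 0.0250),
    ("moderately vs poorly, TPS<50%", 12, 27, 3, 22, 0.0438),
    ("cold(<15) moderately vs extremes", 7, 17, 7, 40, 0.1179),
]
print(f"{'comparison':36s} {'printed':>8s} {'recomputed':>11s}")
for name, dc1, n1, dc2, n2, printed in rows:
    _, p = ps.pairwise_prop_test(dc1, n1, dc2, n2)
    print(f"{name:36s} {printed:>8.4f} {p:>11.4f}")

print("\nknown divergent rows (documented, not asserted):")
for name, dc1, n1, dc2, n2, printed in [
        ("strong vs not strong", 16, 32, 19, 78, 0.0009),
        ("cold(<33) moderately vs extremes", 5, 10, 0, 11, 0.3298)]:
    _, p = ps.pairwise_prop_test(dc1, n1, dc2, n2)
    print(f"{name:36s} {printed:>8.4f} {p:>11.4f}")

data = pd.DataFrame({
    "dc": [1] * 22 + [0] * 22 + [1] * 13 + [0] * 53,
    "proliferation": [True] * 44 + [False] * 66,
})
fit = ps.fit_dc_logistic(data, term_order=("proliferation",))
print(f"\nnull deviance {fit.null_deviance:.2f} on {fit.null_df} df "
      f"(printed: 137.61 on 109)")
row = fit.deviance_table.iloc[0]
print(f"proliferation deviance {row.deviance:.4f}, residual "
      f"{row.resid_deviance:.2f} (printed: 11.1163, 126.49)")
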