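"""Verify a hit compound with a simulated dose-response series.

Simulates per-animal readouts at 0-100 uM for a genuine decreaser and for
an inactive compound, then applies the verification rule: replicated
one-tailed significance (P < 0.01) at the upper concentrations plus a
monotone concentration trend.
"""

import numpy as np

from wormhcs import dose_response, make_dose_series

rng = np.random.default_rng(4)
concentrations = [0, 12.5, 25, 50, 100]
dmso = rng.normal(98.1, 9.0, 520)  # per-animal DMSO control readouts

real = make_dose_series(lambda c: 98.1 - 45.0 * c / 100.0, concentrations,
                        replicates=140, rng=rng)
flat = make_dose_series(lambda c: 98.1, concentrations, replicates=140, rng=rng)

for name, series in (("active decreaser", real), ("inactive compound", flat)):
    res = dose_response(series[series.concentration > 0], dmso, "decrease")
    print(f"{name}: {res.verdict} (Spearman rho {res.spearman_rho:+.2f})")
    for _, row in res.pvalues.iterrows():
        print(f"  {row.concentration:6.1f} uM  mean {row['mean']:6.1f}  "
              f"P {row.p:.2e}")
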