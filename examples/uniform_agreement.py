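"""Reference-band outlier rates when the measurements are not normal.

Both measurements are uniform on [0, 1] with Pearson correlation 0.85.
Two generators with identical marginals and correlation but different
joint laws are compared: a comonotone mixture (x2 equals x1 with
probability rho, independent otherwise) and a Gaussian copula.  The band
assumes bivariate normality, so the outlier rate depends on the joint
shape, not just on the correlation.
"""

import numpy as np

from refband import (
    detect_outliers,
    reference_band,
    sample_ccc,
    sample_correlated_uniform,
)

for method in ("mixture", "gaussian_copula"):
    rates = []
    for run in range(200):
        sample = sample_correlated_uniform(
            0.85, 1000, seed=np.random.SeedSequence([run, 7]), method=method
        )
        band = reference_band(sample, alpha=0.05, rho_L=0.75)
        rates.append(detect_outliers(sample, band).pct_outliers)
    ccc, _, _ = sample_ccc(sample)
    print(
        f"{method:<16} median % outside the band: "
        f"{np.median(rates):4.1f}   (last-run CCC = {ccc:.3f})"
    )

print()
print(
    "Same correlation, different joint distribution: the mixture puts\n"
    "its discordant 15% of pairs anywhere in the unit square, so ~5% of\n"
    "differences escape the band, while the copula's differences are\n"
    "nearly normal and only ~2% escape.  With non-normal data the band's\n"
    "nominal 100(1-alpha)% content is indicative, not exact."
)
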