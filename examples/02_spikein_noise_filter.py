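"""Technical-noise gene filtering with ERCC spike-ins.

Spike-in reads of known concentration estimate how much expression variation
is purely technical; the squared coefficient of variation is modelled as
cv2(mu) = a1/mu + a0 and biological genes are kept only when their variance
significantly exceeds that noise floor.
"""

import numpy as np

from scbiodisc import (
    SyntheticSpec,
    compute_size_factors,
    filter_by_noise,
    fit_technical_noise,
    simulate,
)

# the generator draws spike-ins on the law cv2 = 3/mu + 0.1
ds = simulate(SyntheticSpec(n_cells=300, n_spikeins=60, seed=3))
norm = compute_size_factors(ds.table, "scale_to_median_total")

fit = fit_technical_noise(norm, alpha=0.01, min_biol_disp=0.25)
print(f"fitted noise law: cv2(mu) = {fit.a1:.2f}/mu + {fit.a0:.3f}")
# a1 should be near 3 and a0 near 0.1, the generating values.

kept = filter_by_noise(norm, fit)
print(f"{kept.n_genes} of {int((~ds.table.is_spikein).sum())} genes exceed the "
      "technical noise level")
markers = {g for ms in ds.markers.values() for g in ms}
print(f"{len(markers & set(kept.gene_ids))} of {len(markers)} true cluster markers "
      "survive the filter")
# marker genes differ between clusters, so their total variance is biological
# and they should pass; genes with flat expression are mostly removed.
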