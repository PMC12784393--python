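"""How the high-mode fraction depends on the internal basic site's position.

Builds a fraction-high map over (distance of the internal basic site to the
C-terminus) × (proline count), with bins under 8 records masked, and the
near/far group contrast that summarizes the positional transition.
"""

import numpy as np

from ccsbimodal import (
    SimulationConfig,
    find_basic_sites,
    fraction_high_map,
    make_dataset,
    mode_fraction_by_group,
    separate_dataset,
)

ds = make_dataset(SimulationConfig(n=10000), seed=1)
res = separate_dataset(ds.records, strategy="refit", seed=1)

fmap = fraction_high_map(
    ds.records, res.assignments, "min_internal_site_distance", "proline_count",
    min_count=8,
)
print("distance  fraction high (all proline counts pooled)")
pooled_high = np.nansum(fmap.fraction_high * fmap.counts, axis=1)
pooled_n = np.where(fmap.mask, fmap.counts, 0).sum(axis=1)
for d, h, n in zip(fmap.x_values, pooled_high, pooled_n):
    if n > 0:
        print(f"   {d:2d}       {h / n:.2f}   (n={int(n)})")


def dist(rec):
    return min(find_basic_sites(rec.sequence).cterm_distances)


near = mode_fraction_by_group(ds.records, res.assignments, lambda r: dist(r) <= 5)
far = mode_fraction_by_group(ds.records, res.assignments, lambda r: dist(r) >= 7)
print(f"\ninternal site within 5 of C-terminus : {near.fraction_high:.0%} high"
      f" (n={near.n})")
print(f"internal site at least 7 away        : {far.fraction_low:.0%} low"
      f" (n={far.n})")
print("\nThe high-mode fraction falls monotonically as the internal basic")
print("site moves away from the C-terminus — the planted positional effect")
print("the map is designed to expose.")
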