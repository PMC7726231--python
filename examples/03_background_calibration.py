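"""Recover the unprinted background size N behind published pathway tables.

Legacy array suites printed r (DEGs in the pathway), n (pathway size) and z
per pathway, but not the background universe N. Because z is monotone in N
at fixed counts, a grid search over candidate N against many printed rows
pins it down. Here we do it for the embedded published tables of the
raptor-silencing trophoblast study.
"""

from degpath.enrichment import zscore_counts
from degpath.evaluation import published_calibration
from degpath.published import PATHWAYS_DOWN

fit_down = published_calibration("down")   # R = 487 down-regulated DEGs
fit_up = published_calibration("up")       # R = 252 up-regulated DEGs

print(f"down table: N_hat = {fit_down.N_hat}, "
      f"max |residual| = {fit_down.max_abs_residual:.3f} z units, "
      f"median = {fit_down.median_abs_residual:.3f}")
print(f"up table:   N_hat = {fit_up.N_hat}, "
      f"max |residual| = {fit_up.max_abs_residual:.3f} z units")

name, _, _, r, n, z_printed = PATHWAYS_DOWN[14]  # the ribosome row
print(f"\n{name}: printed z = {z_printed}, "
      f"recomputed at N = 20,000: z = {zscore_counts(r, n, 487, 20_000):.2f}, "
      f"at N_hat: z = {zscore_counts(r, n, 487, fit_down.N_hat):.2f}")
# The two directional tables imply different backgrounds (~20k vs ~32k);
# no single N reconciles them — a genuine inconsistency of the published
# tables that the calibration exposes rather than hides.
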