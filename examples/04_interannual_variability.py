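"""Interannual variability: spectrum, band-pass, noise-corrected 25-yr SDs.

Uses the default scenario, whose true 2-8-yr band SD rises from 0.15 to
0.35 degC at 11.66 kyr b2k, and shows the analytical-noise correction and
the red-noise spectrum of the annual record.
"""

import varvesst as v

cfg = v.ScenarioConfig(seed=11)
res = v.run_full_pipeline(v.RunConfig(scenario=cfg, seed=11))

b = res.variability_blocks
old = b["age_mid"] > cfg.interannual_change_age
print("25-yr block variability (degC):")
print(f"  raw        old era {b.loc[old, 'raw_sd_c'].mean():.3f}   "
      f"young era {b.loc[~old, 'raw_sd_c'].mean():.3f}")
print(f"  corrected  old era {b.loc[old, 'corrected_sd_c'].mean():.3f}   "
      f"young era {b.loc[~old, 'corrected_sd_c'].mean():.3f}")
stat, p = res.variability_test
print(f"  t-test for the change at {cfg.interannual_change_age}: p = {p:.2e}")

spec = res.spectrum
print(f"\nspectrum: AR(1) lag-1 = {spec.ar1_phi:.2f}; significant peaks:")
for band in ((80, 200), (30, 60)):
    try:
        p_yr = v.significant_peak_period(spec, band)
        print(f"  {band[0]}-{band[1]} yr band: peak at {p_yr:.1f} yr")
    except v.NoSignificantPeakError:
        print(f"  {band[0]}-{band[1]} yr band: none above the 95% level")
# The subtraction of the pooled-precision law (0.0741 n^-0.558) removes the
# part of the block SD explained by having fewer spots per varve; the
# young/old contrast that remains is the true interannual change.
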