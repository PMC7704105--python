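"""The three ratio effect sizes from one population's summary statistics.

A population = one strain at one institution. Males in the numerator:
positive values are male-biased. lnVR compares absolute variability (SDs),
lnCVR compares relative variability (CVs), which removes the strong
mean-variance coupling typical of morphological and physiological traits.
"""

from dimorph import ln_cvr, ln_rr, ln_vr, percent_difference

# example: body-mass-like trait, 20 animals per sex
n_m, mean_m, sd_m = 20, 10.0, 2.0
n_f, mean_f, sd_f = 20, 8.0, 1.6

rr, v_rr = ln_rr(n_m, mean_m, sd_m, n_f, mean_f, sd_f)
vr, v_vr = ln_vr(n_m, sd_m, n_f, sd_f)
cvr, v_cvr = ln_cvr(n_m, mean_m, sd_m, n_f, mean_f, sd_f)

print(f"lnRR  = {rr:+.5f} (sampling variance {v_rr:.5f})  "
      f"-> males {percent_difference(rr):.1f}% larger means")
print(f"lnVR  = {vr:+.5f} (sampling variance {v_vr:.5f})  "
      f"-> male SD {percent_difference(vr):.1f}% higher")
print(f"lnCVR = {cvr:+.5f} (sampling variance {v_cvr:.5f})  "
      f"-> equal CVs: no relative-variability difference")
print()
print("Both sexes have CV = 0.2 here, so lnCVR is exactly 0: the higher male")
print("SD is fully explained by the higher male mean. lnCVR = lnVR - lnRR")
print(f"holds for the point estimates at equal n: {vr - rr:+.5f}")
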