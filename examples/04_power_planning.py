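"""Sex-aware sample-size planning when one sex is more variable.

If female SDs are larger (e.g. immunological traits), Neyman allocation
(n_f : n_m = sd_f : sd_m) reaches the target power with fewer animals in
total than a 50:50 split.
"""

from dimorph import PowerQuery, optimal_allocation, required_n

sd_m, sd_f = 1.0, 1.6   # females 60% more variable
effect = 0.8            # mean difference to detect, in trait units

print(f"optimal allocation n_f : n_m = {optimal_allocation(sd_m, sd_f):.2f}")

for allocation in ("equal", "optimal"):
    res = required_n(PowerQuery(effect=effect, sd_m=sd_m, sd_f=sd_f,
                                allocation=allocation))
    print(f"{allocation:8s}: n_m = {res.n_m:3d}, n_f = {res.n_f:3d}, "
          f"total N = {res.n_total:3d}, achieved power = {res.achieved_power:.3f}")

print()
print("The optimal split needs more females than males (N_female > N_male)")
print("and a smaller total N than the equal split at the same power; both use")
print("a two-sided Welch test at alpha = 0.05, power computed from the")
print("noncentral t distribution.")
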