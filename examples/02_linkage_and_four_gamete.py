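"""LD between the M1 and G2 variants, and the four-gamete recombination test.

Without the recombinant lineage the M1-alt/G2-alt gamete never occurs
(p_AB = 0, three gametes); once the recombinant segregates all four gametes
are present — direct evidence for a crossover between the two positions.
"""

import apol1hap as ah

panel = ah.default_panel()
i = panel.index_of_role("M1")
j = panel.index_of_role("G2_del")

for label, freq in [("with recombinant", None), ("no recombinant", 0.0)]:
    kwargs = {} if freq is None else {"recombinant_frequency": freq}
    hm, _ = ah.simulate_population(ah.SimConfig(seed=7, **kwargs))
    fg = ah.four_gamete(hm, i, j)
    res = ah.ld_pair(hm, i, j)
    print(f"{label}: gametes {fg.gamete_counts}  all_four={fg.all_four}")
    print(f"  p_M1={res.p_a:.4f}  p_G2={res.p_b:.4f}  p_M1G2={res.p_ab:.4f}"
          f"  D'={res.d_prime:.3f}  r2={res.r2:.4f}")

# Without the recombinant, D' = 1 signals complete repulsion (the M1-alt /
# G2-alt gamete is absent); sampling the recombinant breaks that repulsion,
# collapsing D' while r2 stays near zero for such rare alleles.
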