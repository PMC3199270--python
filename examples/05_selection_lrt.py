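"""Likelihood-ratio tests between codon site models of the MAT genes.

The packaged table carries externally fitted site-model results for the
three mating-type genes; the LRTs ask whether selective pressure varies
among codons (M0 vs M3) and whether any codon class evolves under positive
selection (M1a vs M2a, M7 vs M8)."""

from cryptosex import load_codon_model_fits, run_lrt_suite, selection_summary

fits = load_codon_model_fits()
lrts = run_lrt_suite(fits)

print(f"{'gene':10s} {'comparison':12s} {'2dlnL':>8s} {'df':>3s} {'p':>8s}")
for r in lrts:
    pair = f"{r.null_model.value} vs {r.alt_model.value}"
    flag = " *" if r.significant else ""
    print(f"{r.gene:10s} {pair:12s} {r.two_delta_lambda:8.4f} {r.df:3d} "
          f"{r.p_value:8.4f}{flag}")

s = selection_summary(fits, lrts)
print(f"\ngene-wide dN/dS range: {s.omega_min:.2f} - {s.omega_max:.2f}")
print(f"variable pressure among sites: {sorted(s.genes_with_variable_pressure)}")
print(f"positive selection supported:  {sorted(s.genes_with_positive_selection_support)}")
for gene, prop, omega in s.positive_site_classes:
    print(f"  {gene}: {100 * prop:.1f}% of sites at omega = {omega:.2f}")
# dN/dS well below 1 for every model: the MAT genes evolve under strong
# purifying selection, i.e. their mating function appears preserved.
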