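"""Spatial co-occurrence of compatible mating types on a sampling grid.

Clone-mates are placed near their source, so a clonal population forms
single-mating-type patches; the coefficient of association Q asks whether
the two mating types are found at the same grid points more often than
chance."""

from cryptosex import (
    SimulationConfig,
    association_q,
    chi_square_independence,
    occupancy_table,
    simulate_population,
)

pop, _ = simulate_population(
    SimulationConfig(n_isolates=120, clonality=0.5, mutation_rate=0.02,
                     patch_spread=1, seed=5)
)
t = occupancy_table(pop)
print(f"grid points: {t.n_grid_points_total}  strains placed: {t.n_strains}")
print(
    f"only MAT1-1: {t.n_only_mat1_1}  only MAT1-2: {t.n_only_mat1_2}  "
    f"both: {t.n_both}  neither: {t.n_neither}"
)
q = association_q(t)
stat, p = chi_square_independence(t)
print(f"Q = {q:+.3f}   chi2(1) = {stat:.3f}   p = {p:.4f}")
# Q > 0: compatible mating types co-occur at grid points more often than
# expected by chance, a spatial prerequisite for mating; Q < 0: the types
# segregate into separate (clonal) patches.
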