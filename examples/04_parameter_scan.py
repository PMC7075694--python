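"""Scan a small (k_b, k_t) grid and read off the field-size surface.

The full default grid covers 49 rate values (0.01-0.97 μm⁻¹, step 0.02)
plus near-critical Δk refinements; here a coarse sub-grid keeps the run
short.  Cells with k_b >= k_t are excluded: there the arbor grows without
bound.
"""

from dendrosim import GridSpec, characteristic_radius, scan

grid = GridSpec(k_values=(0.1, 0.3, 0.5, 0.7, 0.9),
                delta_k_refinements=(0.05,),
                n_neurons_per_cell=50, master_seed=3)
result = scan(grid, n0=30)

print("mean R95 (μm); rows = k_t, columns = k_b; NaN = excluded")
print(result.matrix("mean_r95").round(2).to_string())
print()
ref = result.records.query("refined")
print("Δk = 0.05 refinement cells (radius scale sqrt(1/Δk) ="
      f" {characteristic_radius(0.05):.1f} μm):")
print(ref[["k_b", "k_t", "mean_r95", "cv"]].round(2).to_string(index=False))
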