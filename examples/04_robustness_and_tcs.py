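"""Robustness of the iterative segmentation.

Two checks on seeded synthetic cohorts: (1) the worst-case start-threshold
statistic — rerun every cell's threshold iteration from half and double
the Otsu estimate and measure the mean relative final-area difference;
(2) a target-cell-size sweep showing that the default 500 µm² prior
maximizes detection and accuracy.
"""

from microglia_morph import generate_field, s1_robustness, tcs_sweep

fields = [generate_field(n_cells=20, seed=s) for s in range(3)]
stat = s1_robustness(fields, n_cells_min=40)
print(f"start-threshold robustness: mean |A(T/2) - A(Tx2)| / mean area "
      f"= {stat:.2f}%  (small: the iteration forgets its start)")

print("\ntarget-cell-size sweep on one field:")
df = tcs_sweep(fields[0], [200, 350, 500, 650, 800])
print(df.round(2).to_string(index=False))
print("\na TCS near the true ~500 µm² footprint gives the best area "
      "accuracy; far-off priors under- or over-segment")
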