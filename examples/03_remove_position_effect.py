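"""Partial-effect removal: isolate predictability from the position drift.

The word-position effect is a slow positive drift over the sentence that
overlaps the N400 window and masks the predictability contrast in raw
condition averages.  Subtracting the fitted per-sample position
contribution from the single-trial data (random intercepts retained)
exposes the high-vs-low predictability separation for common sentences.
"""

import lmmcbp as L
from lmmcbp.design import build_design
from lmmcbp.partial import PartialEffectSelection

layout = L.make_layout(12)
truth = L.default_truth(
    layout, n_times=24, dt_ms=800.0 / 24,
    pred_common_amplitude=4.5, position_amplitude=0.6, sd_noise=4.5,
)
corpus = L.simulate_corpus(n_memory=8, n_common=12, seed=11)
epochs, table = L.simulate_epochs(corpus, truth, n_subjects=6, layout=layout, seed=12)
epochs = L.baseline_correct(epochs)
epochs, table = L.apply_word_filter(epochs, table)

stats = L.fit_grid(epochs, table, L.ModelSpec())
design = build_design(table, L.ModelSpec())
selection = PartialEffectSelection(("position:common", "position:memory_encoded"))
cleaned = L.remove_partial(epochs, design, stats, selection)

roi = L.centro_parietal_electrodes(layout)
window = L.TimeWindow(300.0, 450.0)
table = table.copy()
table["pred_tercile"] = L.tercile_split(table["predictability"].to_numpy())

print(f"ROI {roi}, window [300, 450) ms")
print(f"{'data':9s} {'type':16s} {'high-low (uV)':>14s}")
for name, ep in (("original", epochs), ("cleaned", cleaned)):
    avg = L.condition_average(ep, table, ["pred_tercile", "sentence_type"],
                              roi=roi, window=window)
    g = avg.groupby(["pred_tercile", "sentence_type"])["mean"].mean()
    for stype in ("common", "memory_encoded"):
        diff = g[("high", stype)] - g[("low", stype)]
        print(f"{name:9s} {stype:16s} {diff:14.2f}")

# The high-low contrast for common sentences survives the cleaning (it is
# a genuine predictability effect), while memory-encoded sentences show
# essentially none -- their continuation is recalled, not predicted, so
# cloze predictability no longer modulates the N400.
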