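"""Score a synthetic multi-cell-type feature panel.

Builds a 15-cell-type x 6-feature study (225 pairs) with one planted
pair that colocalizes far beyond what its information content predicts,
scores every pair, and prints the top of the ranking. The planted pair
should sit at rank 1 with a small residual p-value; background pairs
hover near score 0.
"""
from macmic import build_manifest, score_panel
from macmic.simulate import simulate_study

features_by_ct, tracks, genes, truth = simulate_study(
    n_genes=150, n_background=80, planted=[("ct02", "F1", "F3")], seed=42
)
manifest = build_manifest(features_by_ct)
print(f"panel: {len(manifest)} feature pairs, {len(genes)} genes")

table = score_panel(manifest, tracks, genes)
print(table.head(5).to_string(index=False))
print(
    "\nplanted pair:", truth["planted"][0],
    "| a large positive score with p << 0.05 means the pair colocalizes"
    " far more often than the panel-wide information-colocalization trend predicts",
)
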