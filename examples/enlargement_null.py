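"""How much CTCF association do super-enhancers owe to their size?

Each typical enhancer is matched to a random super-enhancer and grown
symmetrically to the matched width; comparing CTCF association rates of
the typical, enlarged and super collections separates the contribution
of sheer size from genuine CTCF enrichment at super-enhancers.
"""
from macmic import call_superenhancers, enlarge_typical_enhancers
from macmic.simulate import generate_ctcf_for_enhancers, generate_hockey_stick_enhancers

track, _ = generate_hockey_stick_enhancers(500, 15, signal_ratio=50, seed=5)
ctcf = generate_ctcf_for_enhancers(track, seed=6)

calls = call_superenhancers(track)
supers = [c for c in calls if c.is_super]
typical = [c for c in calls if not c.is_super]

enlarged, rates = enlarge_typical_enhancers(typical, supers, ctcf, seed=7)
for name, value in rates.items():
    print(f"{name:22s} {value:.3f}")
print(
    "\nenlargement closes part of the gap (size matters) but not all of"
    " it: super-enhancers remain more CTCF-associated than size alone explains"
)
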