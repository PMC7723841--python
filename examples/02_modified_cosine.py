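"""Shift-aware cosine: why homologs connect even when their fragments move.

Builds fentanyl-like and alpha-methylfentanyl-like spectra. The methyl
homolog's core fragment moves from 188.143 to 202.159 — exactly the
precursor difference — so the shifted match recovers it.
"""

from molnet import SimilarityParams, Spectrum, modified_cosine
from molnet.spectra_io import Peak


def spec(name, prec, peaks):
    return Spectrum(name, prec, [Peak(m, i) for m, i in peaks], precursor_charge=1)


fentanyl = spec(
    "fentanyl-like", 337.2274,
    [(105.0699, 60), (188.1434, 100), (265.170, 12), (281.165, 15), (309.196, 25)],
)
alpha_methyl = spec(
    "alpha-methyl-like", 351.2431,
    [(105.0699, 60), (202.1590, 100), (279.186, 12), (295.181, 15), (323.212, 25)],
)

for use_shift in (True, False):
    params = SimilarityParams(use_shift=use_shift)
    res = modified_cosine(fentanyl, alpha_methyl, params)
    mode = "with precursor shift" if use_shift else "direct matches only "
    print(f"{mode}: cosine={res.score:.3f}  matched ions={res.n_matched}")

# With the shift the pair scores ~1.0 on 5 matched ions; without it only
# the shared 105.0699 fragment matches and the similarity collapses.
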