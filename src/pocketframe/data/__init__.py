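"""Packaged annotation fixtures.

``y1r_tm.tsv`` / ``y1r_bw.tsv`` annotate the human neuropeptide Y1 receptor
on chain "R". The Ballesteros–Weinstein assignments follow the published
structural literature on Y1R (e.g. W276 = 6.48, Q120 = 3.32); the TM residue
ranges are approximate spans around those anchors, since exact helix limits
vary between deposited models. Both tables are plain TSV and can be replaced
by user-supplied files for any other receptor or chain naming.
"""

from importlib import resources
from pathlib import Path


def y1r_annotation_paths() -> tuple[Path, Path]:
    """Paths of the packaged Y1R (TM ranges, BW codes) tables."""
    base = resources.files(__package__)
    return Path(str(base / "y1r_tm.tsv")), Path(str(base / "y1r_bw.tsv"))


def load_y1r_annotations(chain: str = "R"):
    """Packaged Y1R annotations, re-mapped onto *chain*.

    Deposited Y1R models differ in receptor chain naming (the packaged
    tables use "R"); pass the chain id of the model at hand.
    """
    from ..structure_io import GenericNumberingMap, TMAnnotation, TMHelix, load_annotations

    tm_path, bw_path = y1r_annotation_paths()
    tm, bw = load_annotations(tm_path, bw_path)
    if chain == "R":
        return tm, bw
    tm2 = TMAnnotation(TMHelix(h.helix_id, chain, h.start, h.end) for h in tm)
    bw2 = GenericNumberingMap((chain, resnum, code)
                              for (_c, resnum), code in bw.items())
    return tm2, bw2
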