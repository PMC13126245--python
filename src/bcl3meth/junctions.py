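"""Breakpoint and junction-sequence annotation for IGH::BCL3 rearrangements.

Covers the five questions a sequenced translocation junction raises:

* where does the chr19 breakpoint sit relative to BCL3 (upstream =
  centromeric / downstream = telomeric / within), and which feature
  contains it,
* which functional IGH segment (switch region, J or D gene) contains the
  chr14 breakpoint,
* are recombination-signal sequences (heptamer-spacer-nonamer with a 12- or
  23-base spacer) present near the junction,
* how many untemplated (N) nucleotides or microhomologous bases join the
  two flanks,
* which mechanism best explains the junction: class-switch recombination
  (breakpoint inside a switch region) or aberrant V(D)J recombination
  (breakpoint at J/D genes with a nearby RSS and untemplated insertions).

Coordinates are 1-based inclusive throughout; "upstream" of BCL3 means the
centromeric side, which is the low-coordinate side on 19q.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

import numpy as np
import pandas as pd

from .synth import RSS_HEPTAMER, RSS_NONAMER, JunctionRecord, SyntheticLoci

__all__ = [
    "LocusAnnotation",
    "RSSHit",
    "load_bundled_loci",
    "classify_19q",
    "assign_igh_segment",
    "detect_rss",
    "junction_inserts",
    "infer_mechanism",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class LocusAnnotation:
    """Named features (genes, introns, switch regions, J/D genes) with spans."""

    features: pd.DataFrame  # chrom, start, end, name, feature_class, strand

    def __post_init__(self) -> None:
        sw = self.features[self.features["feature_class"] == "switch_region"].sort_values("start")
        if len(sw) > 1 and not (sw["start"].diff().dropna() > 0).all():
            raise ValueError("switch regions must be ordered along the locus")

    @classmethod
    def from_loci(cls, loci: Union[SyntheticLoci, pd.DataFrame]) -> "LocusAnnotation":
        feats = loci.features if isinstance(loci, SyntheticLoci) else loci
        return cls(features=feats.copy())

    def feature(self, name: str) -> pd.Series:
        hit = self.features[self.features["name"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]

    def containing(self, chrom: str, pos: int, classes: Optional[list[str]] = None) -> pd.DataFrame:
        f = self.features
        m = (f["chrom"] == chrom) & (f["start"] <= pos) & (pos <= f["end"])
        if classes is not None:
            m &= f["feature_class"].isin(classes)
        return f[m]


def load_bundled_loci() -> LocusAnnotation:
    """The shipped hg38-derived IGH / BCL3-region coordinate table."""
    with resources.files("bcl3meth.data").joinpath("igh_bcl3_loci_hg38.tsv").open() as fh:
        feats = pd.read_csv(fh, sep="\t")
    return LocusAnnotation(features=feats)


@dataclass
class RSSHit:
    position: int  # 1-based heptamer start on the forward strand coordinates
    spacer_type: int  # 12 or 23
    strand: str  # "+" or "-"
    mismatches: int


def _as_annotation(loci) -> LocusAnnotation:
    if isinstance(loci, LocusAnnotation):
        return loci
    return LocusAnnotation.from_loci(loci)


def classify_19q(pos: int, loci) -> tuple[str, str]:
    """Relation of a chr19 position to BCL3 plus its containing feature.

    Returns ``(relation, feature)`` with relation in {upstream_of_BCL3,
    downstream_of_BCL3, within_BCL3}.  Upstream is the centromeric
    (low-coordinate) side.  The feature is the innermost containing span
    (intron resolution) or the nearest feature when the position is
    intergenic.
    """
    ann = _as_annotation(loci)
    bcl3 = ann.feature("BCL3")
    if not (ann.features["chrom"] == "chr19").any():
        raise ValueError("annotation lacks chr19 features")
    chrom = str(bcl3["chrom"])
    f19 = ann.features[ann.features["chrom"] == chrom]
    if not (int(f19["start"].min()) - 10**6 <= pos <= int(f19["end"].max()) + 10**6):
        raise ValueError(f"position {pos} not on the annotated {chrom} region")

    if int(bcl3["start"]) <= pos <= int(bcl3["end"]):
        relation = "within_BCL3"
    elif pos < int(bcl3["start"]):
        relation = "upstream_of_BCL3"
    else:
        relation = "downstream_of_BCL3"

    inside = ann.containing(chrom, pos)
    if not inside.empty:
        # innermost span = smallest containing feature (introns beat genes)
        spans = (inside["end"] - inside["start"]).to_numpy()
        feature = str(inside.iloc[int(np.argmin(spans))]["name"])
    else:
        mid = (f19["start"] + f19["end"]) / 2.0
        feature = str(f19.iloc[int((mid - pos).abs().argmin())]["name"])
    return relation, feature


def assign_igh_segment(pos: int, loci) -> Optional[str]:
    """Containing IGH switch region / J gene / D gene label, else None."""
    ann = _as_annotation(loci)
    f14 = ann.features[ann.features["chrom"] == "chr14"]
    if f14.empty:
        raise ValueError("annotation lacks chr14 features")
    hit = ann.containing("chr14", pos, classes=["switch_region", "J_gene", "D_gene"])
    if hit.empty:
        return None
    return str(hit.iloc[0]["name"])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_strand(seq: str, tolerance: int) -> list[tuple[int, int, int]]:
    """(0-based heptamer start, spacer_type, mismatches) on one strand."""
    hits = []
    n = len(seq)
    h, m = len(RSS_HEPTAMER), len(RSS_NONAMER)
    for spacer_type, spacers in ((12, (11, 12, 13)), (23, (22, 23, 24))):
        for i in range(n):
            best = None
            for sp in spacers:
                j = i + h + sp
                if j + m > n:
                    continue
                mism = sum(a != b for a, b in zip(seq[i : i + h], RSS_HEPTAMER))
                if mism > tolerance:
                    continue
                mism += sum(a != b for a, b in zip(seq[j : j + m], RSS_NONAMER))
                if mism <= tolerance and (best is None or mism < best):
                    best = mism
            if best is not None:
                hits.append((i, spacer_type, best))
    return hits


def detect_rss(seq: str, tolerance: int = 1) -> list[RSSHit]:
    """Scan both strands for heptamer-spacer-nonamer RSS motifs.

    Spacer lengths of 12 +/- 1 and 23 +/- 1 are accepted; ``tolerance``
    bounds the total heptamer+nonamer mismatches.  Positions are 1-based
    heptamer starts in the forward coordinates of ``seq`` (for minus-strand
    hits, the start of the reverse-complement heptamer's footprint).
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence may only contain A, C, G, T, N")
    hits = [RSSHit(position=i + 1, spacer_type=st, strand="+", mismatches=mm)
            for i, st, mm in _scan_strand(seq, tolerance)]
    rc = _revcomp(seq)
    n = len(seq)
    for i, st, mm in _scan_strand(rc, tolerance):
        # heptamer occupies rc[i:i+7] -> forward positions n-i-7 .. n-i-1 (0-based)
        hits.append(RSSHit(position=n - i - 7 + 1, spacer_type=st, strand="-", mismatches=mm))
    return sorted(hits, key=lambda h: (h.position, h.strand, h.spacer_type))


def junction_inserts(
    junction_seq: str, left_flank: str, right_flank: str, seed: int = 10
) -> tuple[int, int]:
    """Untemplated-insert and microhomology lengths of a junction.

    ``left_flank`` is the reference sequence ending at the left breakpoint,
    ``right_flank`` the reference starting at the right breakpoint.  The
    maximal suffix of the left flank matching the junction start and the
    maximal prefix of the right flank matching the junction end either
    leave a gap (untemplated insert), overlap (microhomology, present once
    at the join), or abut exactly (blunt join).
    """
    j = junction_seq.upper()
    lf = left_flank.upper()
    rf = right_flank.upper()
    a = 0
    for k in range(min(len(lf), len(j)), 0, -1):
        if j[:k] == lf[-k:]:
            a = k
            break
    b = 0
    for k in range(min(len(rf), len(j)), 0, -1):
        if j[-k:] == rf[:k]:
            b = k
            break
    if a < seed or b < seed:
        raise ValueError(
            f"flank does not align to the junction end (matches {a} and {b} < seed {seed})"
        )
    if a + b < len(j):
        return len(j) - a - b, 0
    if a + b > len(j):
        return 0, a + b - len(j)
    return 0, 0


def infer_mechanism(
    record: JunctionRecord, loci, rss_distance: int = 25
) -> str:
    """Mechanism call for a junction: CSR, VDJ or undetermined.

    CSR: the IGH-side breakpoint lies in a switch region.  VDJ: the
    breakpoint lies in a J/D gene, an RSS heptamer sits within
    ``rss_distance`` bases of the junction point, and the junction carries
    untemplated nucleotides.  CSR takes precedence if both fire.
    """
    ann = _as_annotation(loci)
    segment = assign_igh_segment(record.pos14, ann)
    seg_class = None
    if segment is not None:
        seg_class = str(ann.feature(segment)["feature_class"])
    is_csr = seg_class == "switch_region"

    is_vdj = False
    if seg_class in ("J_gene", "D_gene") and record.left_flank and record.right_flank:
        ins, _mh = junction_inserts(record.junction_seq, record.left_flank, record.right_flank)
        if ins > 0:
            # junction point: end of the matched left flank
            boundary = len(record.left_flank)
            for hit in detect_rss(record.junction_seq):
                h0 = hit.position - 1
                dist = h0 - (boundary + ins) if h0 >= boundary else boundary - (h0 + 7)
                if 0 <= dist <= rss_distance or abs(h0 - boundary) <= rss_distance:
                    is_vdj = True
                    break
    if is_csr:
        return "CSR"
    if is_vdj:
        return "VDJ"
    return "undetermined"
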