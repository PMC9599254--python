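"""Promoter element prediction and operator-promoter overlap classification.

Bacterial sigma70-type promoters consist of a -35 hexamer and a -10 hexamer
separated by a 15-19 bp spacer.  Both elements are located by small PWMs on
the gene's coding strand inside the upstream window.  An operator that
physically overlaps either hexamer blocks RNA polymerase binding, the
architecture expected of a transcriptional repressor; classify_overlap
reports which element (if any) an operator covers.

A bundled synthetic training set (canonical TTGACA / TATAAT families) stands
in for organism-specific promoter compilations when none is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .genome_io import UpstreamRegion
from .pwm import SiteAlignment, WeightMatrix, build_pwm
from .scan import CandidateSite

HEXAMER = 6
DEFAULT_SPACER_BOUNDS = (15, 19)


@dataclass(frozen=True)
class PromoterCall:
    """A (-35, -10) element pair on a gene's coding strand.

    Intervals are half-open indices into the scanned region's sequence;
    ``rel_minus35``/``rel_minus10`` give the biologist-convention relative
    position of each hexamer's first base.
    """

    minus35_start: int
    minus10_start: int
    rel_minus35: int
    rel_minus10: int
    score35: float
    score10: float

    @property
    def spacer(self) -> int:
        return self.minus10_start - (self.minus35_start + HEXAMER)

    @property
    def combined_score(self) -> float:
        return self.score35 + self.score10

    @property
    def minus35_interval(self) -> tuple[int, int]:
        return self.minus35_start, self.minus35_start + HEXAMER

    @property
    def minus10_interval(self) -> tuple[int, int]:
        return self.minus10_start, self.minus10_start + HEXAMER


@dataclass(frozen=True)
class OverlapCall:
    """Operator vs promoter-element intersection and the inferred architecture."""

    locus_tag: str
    element: str          # 'minus35' | 'minus10' | 'both' | 'none'
    overlap_bp: int
    architecture: str     # 'repression-consistent' | 'not-overlapping'


def _load_bundled_hexamers(name: str) -> list[str]:
    text = resources.files("regrec.data").joinpath(name).read_text()
    return [ln.strip().upper() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


def default_training_sets() -> tuple[list[str], list[str]]:
    """The bundled (-35, -10) hexamer training lists."""
    return _load_bundled_hexamers("minus35.txt"), _load_bundled_hexamers("minus10.txt")


def train_promoter_pwms(
    minus35_sites: list[str] | None = None,
    minus10_sites: list[str] | None = None,
    pseudocount: float = 0.5,
) -> tuple[WeightMatrix, WeightMatrix]:
    """Build non-palindromic hexamer PWMs for the -35 and -10 boxes.

    Defaults to the bundled training set.  Requires >= 5 hexamers each.
    """
    if minus35_sites is None or minus10_sites is None:
        d35, d10 = default_training_sets()
        minus35_sites = minus35_sites or d35
        minus10_sites = minus10_sites or d10
    for name, sites in (("-35", minus35_sites), ("-10", minus10_sites)):
        if len(sites) < 5:
            raise ValueError(f"{name} training set needs >= 5 hexamers")
        if any(len(s) != HEXAMER for s in sites):
            raise ValueError(f"{name} training set contains non-hexamer entries")
    pwm35 = build_pwm(SiteAlignment(minus35_sites), palindromic=False,
                      pseudocount=pseudocount)
    pwm10 = build_pwm(SiteAlignment(minus10_sites), palindromic=False,
                      pseudocount=pseudocount)
    return pwm35, pwm10


def training_cutoff(
    pwm35: WeightMatrix,
    pwm10: WeightMatrix,
    minus35_sites: list[str] | None = None,
    minus10_sites: list[str] | None = None,
) -> float:
    """Combined-score cutoff: minimum training -35 score + minimum -10 score.

    The loosest cutoff that would still accept a promoter assembled from the
    weakest training instance of each element.
    """
    if minus35_sites is None or minus10_sites is None:
        d35, d10 = default_training_sets()
        minus35_sites = minus35_sites or d35
        minus10_sites = minus10_sites or d10
    lo35 = min(pwm35.score(s) for s in minus35_sites)
    lo10 = min(pwm10.score(s) for s in minus10_sites)
    return lo35 + lo10


def call_promoters(
    region: UpstreamRegion,
    pwm35: WeightMatrix,
    pwm10: WeightMatrix,
    spacer_bounds: tuple[int, int] = DEFAULT_SPACER_BOUNDS,
    min_score: float = float("-inf"),
) -> list[PromoterCall]:
    """Enumerate (-35, -10) pairs with in-bounds spacer, best first.

    Both hexamers must lie on the coding strand, fully upstream of the start
    codon (i.e. within the negative part of the window).
    """
    lo, hi = spacer_bounds
    if lo > hi or lo < 0:
        raise ValueError("invalid spacer bounds")
    seq = region.sequence
    if len(seq) < 2 * HEXAMER + lo:
        return []
    s35 = pwm35.scan(seq)
    s10 = pwm10.scan(seq)

    # last start index keeping a hexamer fully upstream of position +1
    try:
        upstream_end = region.index_of_rel(-1) + 1
    except ValueError:
        upstream_end = len(seq)

    calls = []
    for i in range(len(s35)):
        if i + HEXAMER > upstream_end:
            break
        for spacer in range(lo, hi + 1):
            j = i + HEXAMER + spacer
            if j >= len(s10) or j + HEXAMER > upstream_end:
                continue
            combined = s35[i] + s10[j]
            if combined >= min_score:
                calls.append(PromoterCall(
                    minus35_start=i,
                    minus10_start=j,
                    rel_minus35=region.rel_of_index(i),
                    rel_minus10=region.rel_of_index(j),
                    score35=float(s35[i]),
                    score10=float(s10[j]),
                ))
    calls.sort(key=lambda c: (-c.combined_score, c.minus35_start))
    return calls


def _intersect(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _rel_offset(rel: int) -> int:
    """Linearize biologist-convention positions (no 0) onto integers."""
    if rel == 0:
        raise ValueError("no position 0 in gene-relative coordinates")
    return rel if rel < 0 else rel - 1


def classify_overlap(operator: CandidateSite, promoter: PromoterCall) -> OverlapCall:
    """Intersect an operator with a promoter's hexamers (gene-relative frame).

    Any positive intersection with the -35 or -10 box is classified
    repression-consistent: a bound repressor would occlude polymerase.
    """
    a0 = _rel_offset(operator.rel_start)
    op = (a0, a0 + len(operator.sequence))
    p35 = _rel_offset(promoter.rel_minus35)
    p10 = _rel_offset(promoter.rel_minus10)
    n35 = _intersect(op, (p35, p35 + HEXAMER))
    n10 = _intersect(op, (p10, p10 + HEXAMER))
    if n35 and n10:
        element, overlap = "both", n35 + n10
    elif n35:
        element, overlap = "minus35", n35
    elif n10:
        element, overlap = "minus10", n10
    else:
        element, overlap = "none", 0
    return OverlapCall(
        locus_tag=operator.locus_tag,
        element=element,
        overlap_bp=overlap,
        architecture="repression-consistent" if overlap else "not-overlapping",
    )
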