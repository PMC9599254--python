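"""Position weight matrices for operator motifs.

The weight convention follows the log-count scheme used by the SignalX /
GenomeExplorer school of regulon reconstruction: for base ``b`` in column
``k`` with site counts ``N(b,k)`` and pseudocount ``p``,

    w(b,k) = ln(N(b,k) + p) - (1/4) * sum_b' ln(N(b',k) + p)

so every column sums to zero and a sequence's score is the plain sum of its
positional weights.  Fixed-score thresholds (such as the 4.3 cutoff used for
NagR operator scans) are meaningful only on this scale.

Palindromic motifs (the NagR operator is a 21-bp palindrome) are handled by
count symmetrization: each training site's reverse complement is added to the
counts before weights are computed, which makes the matrix exactly
self-reverse-complementary and strand-symmetric in scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

NEG_INF = float("-inf")


class AlignmentError(ValueError):
    """Raised for invalid site alignments."""


@dataclass
class SiteAlignment:
    """A gapless alignment of equal-length binding sites.

    ``provenance`` optionally records (genome_id, locus_tag, position) per
    site, parallel to ``sites``.
    """

    sites: list[str]
    provenance: list[tuple] | None = None

    def __post_init__(self):
        if len(self.sites) < 2:
            raise AlignmentError("need at least 2 sites")
        L = len(self.sites[0])
        for s in self.sites:
            if len(s) != L:
                raise AlignmentError(
                    f"sites of unequal length ({len(s)} vs {L}): {s}"
                )
            if set(s) - set(BASES):
                raise AlignmentError(f"site {s!r} contains non-ACGT characters")

    @property
    def length(self) -> int:
        return len(self.sites[0])

    @classmethod
    def from_file(cls, path: str) -> "SiteAlignment":
        """Read sites from plain text (one site per line) or TSV.

        TSV rows are ``site<TAB>genome_id<TAB>locus_tag<TAB>position``; a
        header line starting with 'site' is skipped.
        """
        sites, prov = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].lower() in ("site", "sequence"):
                    continue
                sites.append(fields[0].upper())
                if len(fields) >= 4:
                    prov.append((fields[1], fields[2], int(fields[3])))
        return cls(sites, prov if len(prov) == len(sites) else None)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            if self.provenance:
                fh.write("site\tgenome_id\tlocus_tag\tposition\n")
                for s, (g, t, p) in zip(self.sites, self.provenance):
                    fh.write(f"{s}\t{g}\t{t}\t{p}\n")
            else:
                fh.write("\n".join(self.sites) + "\n")


@dataclass
class WeightMatrix:
    """A fixed-length scoring matrix with retained counts.

    Attributes
    ----------
    weights : (4, L) ndarray
        Log-scale weights, rows in A, C, G, T order; each column sums to 0.
    counts : (4, L) ndarray
        Training counts the weights were derived from (post-symmetrization
        for palindromic matrices), kept so the matrix can be refit.
    threshold : float or None
        Score cutoff used by scanners.
    palindromic : bool
        Whether counts were symmetrized with reverse complements.
    """

    weights: np.ndarray
    counts: np.ndarray
    threshold: float | None = None
    palindromic: bool = False
    pseudocount: float = 0.5

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    # -- scoring ----------------------------------------------------------

    def _extended_weights(self) -> np.ndarray:
        # row 4 = N: -inf so any window containing N can never be a hit
        return np.vstack([self.weights, np.full(self.length, NEG_INF)])

    def score(self, seq: str) -> float:
        """Score one sequence of exactly matrix length (sum of weights)."""
        if len(seq) != self.length:
            raise ValueError(
                f"sequence length {len(seq)} != matrix length {self.length}"
            )
        idx = encode(seq)
        return float(self._extended_weights()[idx, np.arange(self.length)].sum())

    def scan(self, seq: str) -> np.ndarray:
        """Score every length-L window of ``seq``; returns array of len(seq)-L+1.

        Windows containing N score -inf.
        """
        L = self.length
        if len(seq) < L:
            return np.empty(0)
        idx = encode(seq)
        win = np.lib.stride_tricks.sliding_window_view(idx, L)
        return self._extended_weights()[win, np.arange(L)].sum(axis=1)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def reverse_complement(self) -> "WeightMatrix":
        return WeightMatrix(
            weights=self.weights[::-1, ::-1].copy(),
            counts=self.counts[::-1, ::-1].copy(),
            threshold=self.threshold,
            palindromic=self.palindromic,
            pseudocount=self.pseudocount,
        )

    # -- serialization ----------------------------------------------------

    def to_files(self, tsv_path: str, json_path: str | None = None) -> None:
        """Write the matrix as TSV (one row per position, columns A C G T)
        plus a JSON sidecar with length/threshold/palindromic/pseudocount
        and the counts."""
        with open(tsv_path, "w") as fh:
            fh.write("pos\tA\tC\tG\tT\n")
            for k in range(self.length):
                vals = "\t".join(f"{self.weights[i, k]:.10g}" for i in range(4))
                fh.write(f"{k + 1}\t{vals}\n")
        if json_path is None:
            json_path = tsv_path + ".json"
        meta = {
            "length": self.length,
            "threshold": self.threshold,
            "palindromic": self.palindromic,
            "pseudocount": self.pseudocount,
            "counts": self.counts.astype(float).tolist(),
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_files(cls, tsv_path: str, json_path: str | None = None) -> "WeightMatrix":
        rows = []
        with open(tsv_path) as fh:
            header = fh.readline()
            if not header.startswith("pos"):
                raise ValueError(f"{tsv_path}: expected header 'pos A C G T'")
            for line in fh:
                if line.strip():
                    rows.append([float(x) for x in line.split("\t")[1:5]])
        weights = np.array(rows).T
        if json_path is None:
            json_path = tsv_path + ".json"
        try:
            with open(json_path) as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        counts = np.array(meta.get("counts", np.zeros_like(weights).tolist()))
        return cls(
            weights=weights,
            counts=counts,
            threshold=meta.get("threshold"),
            palindromic=bool(meta.get("palindromic", False)),
            pseudocount=float(meta.get("pseudocount", 0.5)),
        )


def encode(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes A=0 C=1 G=2 T=3 N=4."""
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def build_pwm(
    alignment: SiteAlignment,
    palindromic: bool = False,
    pseudocount: float = 0.5,
    threshold: float | None = None,
) -> WeightMatrix:
    """Build a weight matrix from aligned sites.

    With ``palindromic=True`` the reverse complement of every site is added
    to the counts before computing weights, forcing self-reverse-complement
    symmetry (appropriate for dyad operators bound by homodimeric TFs).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    L = alignment.length
    counts = np.zeros((4, L))
    for s in alignment.sites:
        counts[encode(s), np.arange(L)] += 1
    if palindromic:
        counts = counts + counts[::-1, ::-1]
    logs = np.log(counts + pseudocount)
    weights = logs - logs.mean(axis=0, keepdims=True)
    return WeightMatrix(
        weights=weights,
        counts=counts,
        threshold=threshold,
        palindromic=palindromic,
        pseudocount=pseudocount,
    )


def score_sequence(pwm: WeightMatrix, seq: str) -> float:
    """Score a single L-mer against the matrix (module-level convenience)."""
    return pwm.score(seq)


def information_content(pwm: WeightMatrix) -> tuple[np.ndarray, float]:
    """Per-column information content in bits, and its total.

    Computed from the retained raw count frequencies without pseudocount:
    ``IC_k = 2 + sum_b f(b,k) log2 f(b,k)`` with ``0*log 0 = 0``.
    """
    colsum = pwm.counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("matrix has no retained counts; IC undefined")
    freqs = pwm.counts / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + terms.sum(axis=0)
    return ic, float(ic.sum())


def logo_table(pwm: WeightMatrix) -> "list[dict]":
    """Per-column base frequencies + IC, ready to dump as a logo-data TSV."""
    colsum = pwm.counts.sum(axis=0)
    freqs = pwm.counts / colsum
    ic, _ = information_content(pwm)
    rows = []
    for k in range(pwm.length):
        row = {"pos": k + 1, "ic_bits": float(ic[k])}
        row.update({b: float(freqs[i, k]) for i, b in enumerate(BASES)})
        rows.append(row)
    return rows


def calibrate_threshold(
    pwm: WeightMatrix,
    rule: str = "fixed",
    value: float | None = None,
    alignment: SiteAlignment | None = None,
) -> float:
    """Derive a scan threshold for a matrix.

    Rules
    -----
    fixed
        Return ``value`` verbatim (e.g. the 4.3 cutoff used for NagR scans
        on the log-count scale).
    min_training_site
        Minimum score of the training alignment's sites: the loosest cutoff
        that still recovers every known site.
    percentile
        ``value``-th percentile (0..100) of training-site scores.
    relative_max
        ``value`` (a fraction in (0, 1]) times the maximum attainable score;
        the scale-free convention common in PWM scanning.
    """
    if rule == "fixed":
        if value is None:
            raise ValueError("fixed rule requires a value")
        return float(value)
    if rule == "relative_max":
        if value is None or not 0 < value <= 1:
            raise ValueError("relative_max requires a fraction in (0, 1]")
        return float(value) * pwm.max_score()
    if rule in ("min_training_site", "percentile"):
        if alignment is None:
            raise ValueError(f"{rule} rule requires the training alignment")
        scores = np.array([pwm.score(s) for s in alignment.sites])
        if rule == "min_training_site":
            return float(scores.min())
        if value is None or not 0 <= value <= 100:
            raise ValueError("percentile must be in [0, 100]")
        return float(np.percentile(scores, value, method="lower"))
    raise ValueError(f"unknown threshold rule {rule!r}")
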