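"""Kimura 2-parameter divergence and neighbor-joining phylogenetics.

The K2P distance separates transition (P) and transversion (Q) proportions:

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

and is reported here multiplied by 100 ("percent" units), matching the 0-60
axis convention of repeat divergence landscapes. Columns containing a gap or
an N in either row are excluded; alignments where the logarithm's argument
is non-positive are *saturated* and raise :class:`KimuraSaturationError` so
callers can exclude-and-count them rather than clamp them into the last bin.

Element-vs-consensus K values, binned into unit bins over [0, 60] and
stratified by species and copy-number class, form the divergence landscape.
Pairwise K2P matrices from an input MSA (pairwise deletion) feed a
Saitou-Nei neighbor-joining implementation that is exact on additive
matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import AlignmentRecord

K_BIN_MAX = 60  # final bin absorbs K >= 60


class KimuraSaturationError(ValueError):
    """The alignment is too diverged for the K2P log to be defined."""


# base encoding for vectorised column classification
_CODE = np.full(256, -1, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
_PURINE = np.array([True, False, True, False])  # A, G


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _k2p_from_codes(x: np.ndarray, y: np.ndarray, what: str) -> float:
    valid = (x >= 0) & (y >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError(f"{what}: no scorable columns")
    xv, yv = x[valid], y[valid]
    diff = xv != yv
    transitions = int((diff & (_PURINE[xv] == _PURINE[yv])).sum())
    transversions = int(diff.sum()) - transitions
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise KimuraSaturationError(f"{what}: saturated (P={p:.3f}, Q={q:.3f})")
    return -50.0 * math.log(w1 * math.sqrt(w2))


def kimura_k2p(rec: AlignmentRecord) -> float:
    """K2P distance (percent) between an element and its consensus.

    Only columns where both rows are a plain A/C/G/T base are scored.
    Raises :class:`KimuraSaturationError` when the distance is undefined and
    ``ValueError`` when no column is scorable.
    """
    return _k2p_from_codes(
        _encode(rec.aligned_element),
        _encode(rec.aligned_consensus),
        f"hit {rec.hit_id} ({rec.family_id})",
    )


@dataclass(slots=True)
class KimuraProfile:
    """Binned K histograms per (species, copy class).

    ``counts`` maps (species, copy_class) to an integer vector of length 61:
    unit bins [k, k+1) for k = 0..59 plus a final bin absorbing K >= 60.
    Saturated and unscorable elements are tallied in ``saturated``.
    """

    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    saturated: dict[tuple[str, str], int] = field(default_factory=dict)
    skipped_no_class: int = 0

    def total_scored(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def mode_bin(self, species: str | None = None, smooth_window: int = 1) -> int:
        """Bin index of the pooled histogram's peak.

        ``smooth_window`` > 1 applies a centred moving average of that odd
        width before taking the argmax. Divergence landscapes are flat near
        their peak (a unit bin is narrow relative to the age spread), so
        the raw argmax wanders between near-tied bins; the smoothed argmax
        is the stable mode readout.
        """
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        pooled = np.zeros(K_BIN_MAX + 1, dtype=np.int64)
        for (sp, _), vec in self.counts.items():
            if species is None or sp == species:
                pooled += vec
        if pooled.sum() == 0:
            raise ValueError("empty profile")
        if smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            return int(np.convolve(pooled, kernel, mode="same").argmax())
        return int(pooled.argmax())

    def to_rows(self) -> list[tuple[str, str, int, int]]:
        rows = []
        for (sp, cls), vec in sorted(self.counts.items()):
            for k, count in enumerate(vec):
                rows.append((sp, cls, k, int(count)))
        return rows


def k_bin(k: float) -> int:
    """Floor binning into unit bins; the final bin absorbs K >= 60."""
    return min(int(math.floor(k)), K_BIN_MAX)


def kimura_profile(
    records_by_species: Mapping[str, Sequence[AlignmentRecord]],
    copy_class: Mapping[tuple[str, str], str],
    strict: bool = True,
) -> KimuraProfile:
    """Histogram element-vs-consensus K per species and copy class.

    ``copy_class`` maps (species, family_id) to LOW/MID/HIGH. With
    ``strict`` (the default) a record whose family has no class raises; when
    relaxed such records are counted in ``skipped_no_class`` instead, which
    is the pipeline behaviour for families below the per-species presence
    floor.
    """
    profile = KimuraProfile()
    for species, records in records_by_species.items():
        for rec in records:
            key = (species, rec.family_id)
            cls = copy_class.get(key)
            if cls is None:
                if strict:
                    raise ValueError(
                        f"no copy class for family {rec.family_id} in {species}"
                    )
                profile.skipped_no_class += 1
                continue
            try:
                k = kimura_k2p(rec)
            except (KimuraSaturationError, ValueError):
                profile.saturated[(species, cls)] = (
                    profile.saturated.get((species, cls), 0) + 1
                )
                continue
            vec = profile.counts.setdefault(
                (species, cls), np.zeros(K_BIN_MAX + 1, dtype=np.int64)
            )
            vec[k_bin(k)] += 1
    return profile


# ---------------------------------------------------------------------------
# Distance matrices and neighbor joining


@dataclass(slots=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")


def k2p_distance_matrix(msa: str | Path | Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise K2P matrix (percent) from an aligned FASTA or (id, seq) pairs.

    Uses pairwise deletion: for each pair, only columns where both taxa have
    a plain base are scored. A saturated pair raises, naming the pair, since
    neighbor joining needs a complete matrix.
    """
    if isinstance(msa, (str, Path)):
        from Bio import SeqIO

        pairs = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(msa), "fasta")
        ]
    else:
        pairs = [(name, seq.upper()) for name, seq in msa]
    if len(pairs) < 3:
        raise ValueError("need at least 3 taxa")
    lengths = {len(seq) for _, seq in pairs}
    if len(lengths) != 1:
        raise ValueError("MSA rows are not all the same length")
    labels = [name for name, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels in MSA")
    codes = [_encode(seq) for _, seq in pairs]
    n = len(pairs)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _k2p_from_codes(
                codes[i], codes[j], f"pair ({labels[i]}, {labels[j]})"
            )
    return DistanceMatrix(labels=labels, d=d)


def _fmt_branch(x: float) -> str:
    return f"{x:.10g}"


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Iteratively joins the pair minimising the Q criterion
    ``(n-2)*d(i,j) - r_i - r_j`` (ties: first pair in label order), with the
    standard branch-length formulas; the last three nodes are resolved by
    the three-point formulas into a trifurcation. Exact on additive
    matrices. Negative branch lengths are clamped to zero unless
    ``clamp_negative=False``.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes = list(dm.labels)  # Newick fragments

    def branch(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = branch(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = branch(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        merged = f"({nodes[i]}:{_fmt_branch(li)},{nodes[j]}:{_fmt_branch(lj)})"
        keep = [k for k in range(m) if k not in (i, j)]
        new_row = np.array([0.5 * (d[i, k] + d[j, k] - d[i, j]) for k in keep])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [merged]

    # three-point resolution of the final trifurcation
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = branch(0.5 * (dab + dac - dbc))
    lb = branch(0.5 * (dab + dbc - dac))
    lc = branch(0.5 * (dac + dbc - dab))
    return (
        f"({nodes[0]}:{_fmt_branch(la)},{nodes[1]}:{_fmt_branch(lb)},"
        f"{nodes[2]}:{_fmt_branch(lc)});"
    )
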