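"""Hi-C-style contact maps from trajectories and domain-structure scoring.

Contacts are scored at bead (400 bp) resolution: a frame contributes a count
for every bead pair within the capture radius (default 1.5 sigma = 15 nm,
minimum image).  Maps can be block-averaged to Hi-C resolution (25 beads =
10 kb).  Self-interacting domains appear as triangles of enriched contacts;
they are quantified by intra/inter contact ratios at matched genomic
separation, insulation-minimum boundary calls, and (for the cohesin-barrier
model) contact-depletion lines at ring anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from .dynamics import Trajectory
from .model import DomainLayout
from .units import BP_PER_BEAD

__all__ = [
    "ContactMatrix",
    "DomainScore",
    "contact_map",
    "bin_map",
    "domain_contact_scores",
    "insulation_profile",
    "boundary_coincidence",
    "depletion_lines",
    "plot_contact_map",
    "write_dense_matrix",
    "read_dense_matrix",
    "write_triplets",
]


@dataclass
class ContactMatrix:
    """Symmetric contact counts with binning metadata.

    At bead resolution ``counts`` are integers; binned views hold tile means
    (floats).  The diagonal is zero by construction (i != j); the adjacent
    band |i-j| = 1 is included in the counts but reported separately by
    :meth:`adjacent_mean`, and scoring functions exclude it by default.
    """

    counts: np.ndarray
    n_frames: int
    cutoff: float
    bin_beads: int = 1

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bp_per_bin(self) -> int:
        return self.bin_beads * BP_PER_BEAD

    def frequency(self) -> np.ndarray:
        """Counts normalised per frame."""
        return self.counts / max(self.n_frames, 1)

    def adjacent_mean(self) -> float:
        """Mean count on the |i-j| = 1 band (bonded neighbours)."""
        return float(np.diagonal(self.counts, 1).mean())

    def validate(self) -> None:
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("negative contact counts")


def contact_map(
    trajectory: Trajectory | np.ndarray,
    cutoff: float = 1.5,
    box: float | None = None,
    first_frame: int = 0,
) -> ContactMatrix:
    """Accumulate bead-bead contacts (min-image distance <= cutoff) over frames."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if isinstance(trajectory, Trajectory):
        frames = trajectory.bead_frames()[first_frame:]
        box = trajectory.box if box is None else box
    else:
        frames = np.asarray(trajectory, float)
        if frames.ndim == 2:
            frames = frames[None]
        frames = frames[first_frame:]
        box = 0.0 if box is None else box
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    n = frames.shape[1]
    counts = np.zeros((n, n), dtype=np.int64)
    K.contact_counts(np.ascontiguousarray(frames), n, box, cutoff, counts)
    return ContactMatrix(counts=counts, n_frames=frames.shape[0], cutoff=cutoff)


def bin_map(matrix: ContactMatrix, bin_beads: int) -> ContactMatrix:
    """Block-average to ``bin_beads`` resolution (25 beads = 10 kb).

    The last partial tile is averaged over its true size, so a constant map
    stays constant and the full-map mean is conserved for divisible sizes.
    """
    if bin_beads < 1:
        raise ValueError("bin_beads must be >= 1")
    if bin_beads == 1:
        return replace(matrix, counts=matrix.counts.copy())
    n = matrix.n_bins
    edges = np.arange(0, n + bin_beads, bin_beads)
    edges[-1] = min(edges[-1], n)
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    nb = len(edges) - 1
    out = np.empty((nb, nb), float)
    c = matrix.counts
    for a in range(nb):
        for b in range(nb):
            tile = c[edges[a] : edges[a + 1], edges[b] : edges[b + 1]]
            out[a, b] = tile.mean()
    return ContactMatrix(
        counts=out,
        n_frames=matrix.n_frames,
        cutoff=matrix.cutoff,
        bin_beads=matrix.bin_beads * bin_beads,
    )


@dataclass
class DomainScore:
    """Contact enrichment of one divergent-transcription domain."""

    domain: int
    bead_range: tuple[int, int]
    intra_mean: float
    inter_mean: float
    ratio: float


def _separation_means(
    m: np.ndarray, rows: range, cols: range, s_values: np.ndarray
) -> np.ndarray:
    """Mean contact at each |i-j| separation for pairs in rows x cols."""
    out = np.full(len(s_values), np.nan)
    ri = np.fromiter(rows, int)
    ci = np.fromiter(cols, int)
    sep = np.abs(ri[:, None] - ci[None, :])
    vals = m[np.ix_(ri, ci)]
    for k, s in enumerate(s_values):
        mask = sep == s
        if mask.any():
            out[k] = vals[mask].mean()
    return out


def domain_contact_scores(
    matrix: ContactMatrix,
    layout: DomainLayout,
    s_min: int = 2,
    s_max: int | None = None,
) -> list[DomainScore]:
    """Intra- vs inter-domain contact frequency at matched separations.

    For each domain, the mean contact between bead pairs inside the domain is
    compared with pairs straddling its borders at the same |i-j| genomic
    separations; their ratio is ~1 for a featureless map and >> 1 for
    TAD-like self-interacting domains.
    """
    m = matrix.counts.astype(float)
    domains = sorted(layout.domains)
    scores = []
    for d, (a, b) in enumerate(domains):
        if b > matrix.n_bins or b - a < s_min + 2:
            raise ValueError(f"domain {d} range ({a},{b}) unusable for matrix")
        length = b - a
        hi = s_max or length - 1
        s_values = np.arange(s_min, hi + 1)
        intra = _separation_means(m, range(a, b), range(a, b), s_values)
        inters = []
        if d > 0:
            a2, b2 = domains[d - 1]
            inters.append(_separation_means(m, range(a2, b2), range(a, b), s_values))
        if d < len(domains) - 1:
            a2, b2 = domains[d + 1]
            inters.append(_separation_means(m, range(a, b), range(a2, b2), s_values))
        if not inters:
            inter = np.full_like(intra, np.nan)
        else:
            stacked = np.vstack(inters)
            inter = np.full(stacked.shape[1], np.nan)
            has_data = ~np.all(np.isnan(stacked), axis=0)
            inter[has_data] = np.nanmean(stacked[:, has_data], axis=0)
        ok = ~np.isnan(intra) & ~np.isnan(inter)
        intra_mean = float(np.nanmean(intra[ok])) if ok.any() else np.nan
        inter_mean = float(np.nanmean(inter[ok])) if ok.any() else np.nan
        ratio = (
            intra_mean / inter_mean
            if inter_mean and inter_mean > 0
            else np.inf
            if intra_mean > 0
            else 1.0
        )
        scores.append(
            DomainScore(
                domain=d,
                bead_range=(a, b),
                intra_mean=intra_mean,
                inter_mean=inter_mean,
                ratio=float(ratio),
            )
        )
    return scores


def insulation_profile(matrix: ContactMatrix, window: int = 5) -> np.ndarray:
    """Sliding-diamond insulation score per bin (NaN near the edges)."""
    m = matrix.counts.astype(float)
    n = matrix.n_bins
    ins = np.full(n, np.nan)
    for i in range(window, n - window):
        ins[i] = m[i - window : i, i + 1 : i + 1 + window].mean()
    return ins


def boundary_coincidence(
    matrix: ContactMatrix,
    layout: DomainLayout,
    window: int = 5,
    min_depth: float = 0.2,
    min_signal: float = 1.0,
) -> dict:
    """Call insulation-minimum boundaries and measure distance to the layout.

    A bin is a boundary when it is the local minimum of the insulation score
    within +-window, the dip below the flanking maxima exceeds ``min_depth``
    (relative), and the flanking insulation has at least ``min_signal`` mean
    counts per diamond pixel (no calls on sampling noise of sparse maps).
    Distances are reported in bins to the nearest motor-convergence border
    of the layout.
    """
    ins = insulation_profile(matrix, window)
    n = matrix.n_bins
    boundaries = []
    for i in range(window, n - window):
        seg = ins[max(0, i - window) : i + window + 1]
        if np.isnan(ins[i]) or np.nanmin(seg) < ins[i]:
            continue
        left_slice = ins[max(0, i - window) : i]
        right_slice = ins[i + 1 : i + 1 + window]
        if not (np.isfinite(left_slice).any() and np.isfinite(right_slice).any()):
            continue
        flank = min(np.nanmax(left_slice), np.nanmax(right_slice))
        if not np.isfinite(flank) or flank < min_signal:
            continue
        if (flank - ins[i]) / flank >= min_depth:
            boundaries.append(i)
    # insulation minima come as short plateaus; report each run's centre
    dedup: list[int] = []
    run: list[int] = []
    for b in boundaries + [None]:
        if run and (b is None or b - run[-1] > 1):
            dedup.append((run[0] + run[-1] + 1) // 2)
            run = []
        if b is not None:
            run.append(b)
    border_bins = [b // matrix.bin_beads for b in layout.borders]
    distances = [
        min((abs(b - bb) for bb in border_bins), default=np.nan) for b in dedup
    ]
    return {"boundaries": dedup, "distances": distances, "insulation": ins}


def depletion_lines(
    matrix: ContactMatrix,
    ring_anchors: list[int],
    band: int = 1,
    gap: int = 2,
    flank: int = 3,
    min_sep: int = 2,
) -> np.ndarray:
    """Contact-depletion score of the row/column band at each ring anchor.

    Score = mean count in the anchor's +-band rows over mean count in
    flanking rows at matched column ranges, ignoring the near-diagonal
    (|i-j| <= min_sep).  Scores < 1 mean the ring shields its anchor's
    contacts; ~1 means no depletion.
    """
    m = matrix.counts.astype(float)
    n = matrix.n_bins
    scores = np.empty(len(ring_anchors))
    for k, a in enumerate(ring_anchors):
        rows_band = [r for r in range(a - band, a + band + 1) if 0 <= r < n]
        rows_flank = [
            r
            for r in list(range(a - band - gap - flank, a - band - gap))
            + list(range(a + band + gap + 1, a + band + gap + flank + 1))
            if 0 <= r < n
        ]
        cols = np.arange(n)

        def band_mean(rows):
            vals = []
            for r in rows:
                sel = np.abs(cols - r) > min_sep
                vals.append(m[r, sel])
            return np.concatenate(vals).mean()

        b_mean = band_mean(rows_band)
        f_mean = band_mean(rows_flank)
        scores[k] = b_mean / f_mean if f_mean > 0 else np.nan
    return scores


# ---------------------------------------------------------------------------
# plain-text I/O (dense and sparse-triplet)
# ---------------------------------------------------------------------------


def write_dense_matrix(matrix: ContactMatrix, path) -> None:
    """Whitespace-delimited dense text with a metadata comment header."""
    header = (
        f"supercoilsim contact matrix; n_frames={matrix.n_frames} "
        f"cutoff={matrix.cutoff} bin_beads={matrix.bin_beads}"
    )
    np.savetxt(path, matrix.counts, header=header)


def read_dense_matrix(path, bin_beads: int = 1, cutoff: float = np.nan) -> ContactMatrix:
    """Read a dense whitespace-delimited matrix (e.g. an external Hi-C bin map)."""
    counts = np.loadtxt(path)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("expected a square dense matrix")
    counts = 0.5 * (counts + counts.T)  # symmetrise defensively
    return ContactMatrix(counts=counts, n_frames=1, cutoff=cutoff, bin_beads=bin_beads)


def plot_contact_map(
    matrix: ContactMatrix, path, log: bool = False, cmap: str = "Reds"
) -> None:
    """Render the map to an image file; linear or logarithmic colour scale.

    The underlying numbers should always be taken from the exported plain
    matrices, never from pixels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    counts = matrix.counts.astype(float)
    fig, ax = plt.subplots(figsize=(5, 5))
    norm = LogNorm(vmin=max(counts[counts > 0].min(), 1e-3), vmax=counts.max()) \
        if log and (counts > 0).any() else None
    im = ax.imshow(counts, cmap=cmap, norm=norm, origin="upper")
    fig.colorbar(im, ax=ax, shrink=0.8, label="contacts")
    kb = matrix.bp_per_bin / 1000.0
    ax.set_xlabel(f"bin ({kb:g} kb)")
    ax.set_ylabel(f"bin ({kb:g} kb)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_triplets(matrix: ContactMatrix, path) -> None:
    """Sparse upper-triangle triplets (bin1, bin2, count), tab-separated."""
    i, j = np.nonzero(np.triu(matrix.counts))
    with open(path, "w") as fh:
        fh.write("# bin1\tbin2\tcount\n")
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{matrix.counts[a, b]:g}\n")
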