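"""Mutation profiles around insertion/excision anchors and gradient fitting.

For every classified polymorphism the substitutions and InDels of its
locus alignment are re-indexed by signed distance from the
insertion/excision point, measured in the coordinates of the genome
*lacking* the TE (there the anchor is a single base position).  Events
are pooled over loci, divided by the pooled aligned coverage at each
offset, and smoothed with the sliding windows also used for plotting
(400/40 bp for substitutions, 1000/100 bp for InDels).

The excision gradient is summarized by fitting

    density(d) = b * (1 + (A_obs - 1) * exp(-|d| / L))

to the substitution density profile.  Because the pairwise density
baseline ``b`` sums the background of *both* lineages while the
repair-induced excess arises in the excised lineage only, the
fold-increase experienced by that lineage is ``2 * A_obs - 1``
(exposed as :attr:`GradientFit.amplitude_excised_lineage`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from tescar.align_core import LocusAlignment, extract_events
from tescar.polymorphisms import PolymorphismCall


def collect_flanks(
    pairs: list[tuple[PolymorphismCall, LocusAlignment]],
    min_aligned: int = 7000,
) -> list[tuple[PolymorphismCall, LocusAlignment]]:
    """Keep loci where more than ``min_aligned`` bases could be aligned."""
    return [(call, aln) for call, aln in pairs if aln.aligned_bases > min_aligned]


@dataclass
class FlankProfile:
    """Pooled per-offset mutation counts around anchors.

    Arrays are indexed by ``offset + flank_extent`` for offsets in
    ``[-flank_extent, +flank_extent]``.
    """

    anchor_class: str
    n_alignments: int
    flank_extent: int
    sub_counts: np.ndarray
    indel_counts: np.ndarray
    coverage: np.ndarray
    window_sub: int = 400
    step_sub: int = 40
    window_indel: int = 1000
    step_indel: int = 100

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank_extent, self.flank_extent + 1)

    def windowed(self, kind: str = "substitution", min_coverage_frac: float = 0.25):
        """(window centers, pooled densities, validity mask).

        Density is pooled counts over pooled coverage per window;
        windows whose mean per-locus coverage falls below
        ``min_coverage_frac`` of the number of alignments are masked.
        """
        if kind == "substitution":
            counts, window, step = self.sub_counts, self.window_sub, self.step_sub
        elif kind == "indel":
            counts, window, step = self.indel_counts, self.window_indel, self.step_indel
        else:
            raise ValueError(f"unknown kind {kind!r}")
        n = counts.size
        centers, dens, mask = [], [], []
        for start in range(0, n - window + 1, step):
            c = counts[start : start + window].sum()
            cov = self.coverage[start : start + window].sum()
            centers.append(start + window / 2.0 - self.flank_extent)
            dens.append(c / cov if cov > 0 else 0.0)
            mask.append(cov >= min_coverage_frac * self.n_alignments * window)
        return np.array(centers), np.array(dens), np.array(mask)


def build_profile(
    selected: list[tuple[PolymorphismCall, LocusAlignment]],
    anchor_class: str = "excision",
    flank_extent: int = 12_000,
    window_sub: int = 400,
    step_sub: int = 40,
    window_indel: int = 1000,
    step_indel: int = 100,
    junction_pad: int = 15,
) -> FlankProfile:
    """Aggregate mutation events relative to each call's anchor.

    The TE gap itself (the disrupted zone found during classification,
    padded by ``junction_pad`` columns) is excluded so the footprint of
    the polymorphism does not masquerade as flanking mutations.
    """
    if not selected:
        return FlankProfile(
            anchor_class, 0, flank_extent,
            np.zeros(2 * flank_extent + 1), np.zeros(2 * flank_extent + 1),
            np.zeros(2 * flank_extent + 1),
            window_sub, step_sub, window_indel, step_indel,
        )
    size = 2 * flank_extent + 1
    sub_counts = np.zeros(size)
    indel_counts = np.zeros(size)
    coverage = np.zeros(size)
    for call, aln in selected:
        # convention: the carrier genome is row A of each locus alignment,
        # matching how the classifier reported its anchors
        col_nc = aln.col_to_b
        anchor = call.anchor_noncarrier
        z0 = call.details.get("zone_col_start", call.anchor_column) - junction_pad
        z1 = call.details.get("zone_col_end", call.anchor_column) + junction_pad

        # zone columns contribute neither events nor coverage
        bb = aln.base_both_mask.copy()
        bb[max(0, z0) : z1] = False
        offs = col_nc[bb] - anchor
        valid = (offs >= -flank_extent) & (offs <= flank_extent)
        np.add.at(coverage, offs[valid] + flank_extent, 1)

        for ev in extract_events(aln):
            if z0 <= ev.position < z1:
                continue
            off = int(col_nc[ev.position]) - anchor
            if -flank_extent <= off <= flank_extent:
                idx = off + flank_extent
                if ev.kind == "substitution":
                    sub_counts[idx] += 1
                else:
                    indel_counts[idx] += 1
    return FlankProfile(
        anchor_class, len(selected), flank_extent,
        sub_counts, indel_counts, coverage,
        window_sub, step_sub, window_indel, step_indel,
    )


@dataclass
class GradientFit:
    amplitude: float  # A_obs: fold over the pairwise baseline at offset 0
    scale: float  # L in bp
    baseline: float  # events per aligned bp, far from the anchor
    residual: float

    @property
    def amplitude_excised_lineage(self) -> float:
        """Fold-increase in the lineage that excised the TE.

        The pairwise baseline contains the background of both lineages
        but the excess is contributed by one, so A = 2 * A_obs - 1.
        """
        return 2.0 * self.amplitude - 1.0


def plot_profile(profile: FlankProfile, path, kind: str = "substitution") -> None:
    """Density-versus-offset plot of a flank profile (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers, dens, mask = profile.windowed(kind)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(centers[mask], dens[mask], lw=1.2)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel(f"{kind}s per aligned bp")
    ax.set_title(f"{profile.anchor_class} profile (n={profile.n_alignments})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fit_gradient(profile: FlankProfile, min_windows: int = 20) -> GradientFit:
    """Least-squares fit of the exponential-decay model to the
    substitution density profile."""
    centers, dens, mask = profile.windowed("substitution")
    x = np.abs(centers[mask])
    y = dens[mask]
    if x.size < min_windows:
        raise ValueError(f"profile has {x.size} usable windows; need >= {min_windows}")
    if not np.any(y > 0):
        raise ValueError("degenerate profile: all densities are zero")

    far = y[x > 0.5 * profile.flank_extent]
    b0 = float(np.median(far)) if far.size else float(np.median(y))
    b0 = max(b0, 1e-9)
    a0 = max(1.0, float(y[np.argmin(x)]) / b0)

    def model(d, b, a, scale):
        return b * (1.0 + (a - 1.0) * np.exp(-d / scale))

    popt, _ = curve_fit(
        model, x, y,
        p0=[b0, a0, 1000.0],
        bounds=([1e-12, 0.0, 1.0], [np.inf, np.inf, np.inf]),
        maxfev=20_000,
    )
    resid = float(np.sqrt(np.mean((model(x, *popt) - y) ** 2)))
    return GradientFit(amplitude=float(popt[1]), scale=float(popt[2]),
                       baseline=float(popt[0]), residual=resid)
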