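"""Per-miRNA significance cutoffs from the shuffled-genome cluster-size tail.

The number of shuffled-genome clusters of a given size decays roughly
exponentially with size; fitting log10(count) = a * size + b over the
top-10% largest clusters and extrapolating to the count expected once in
1000 randomizations gives an integer minimum significant cluster size:

    x_cutoff = ceil((log10(1/1000) - b) / a)

Real-genome clusters at least that large are called significant.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .site_clustering import Cluster

__all__ = ["TailFit", "size_histogram", "fit_tail", "significant_clusters", "cutoff_from_fit"]


@dataclass
class TailFit:
    mirna_id: str
    a: float | None  # slope, log10 count per unit size; < 0 for a valid fit
    b: float | None  # intercept
    x_cutoff: int | None
    p: float = 0.001
    n_clusters_fit: int = 0
    top_frac: float = 0.10

    @property
    def valid(self) -> bool:
        return self.a is not None and self.a < 0 and self.x_cutoff is not None


def size_histogram(clusters: list[Cluster], min_size: int = 2) -> dict[int, int]:
    """Counts per integer cluster size over clusters with size >= min_size."""
    return dict(sorted(Counter(c.size for c in clusters if c.size >= min_size).items()))


def cutoff_from_fit(a: float, b: float, p: float = 0.001) -> int:
    """Integer size cutoff extrapolated from a fitted log-linear tail.

    A 1e-9 guard keeps float noise in the fitted coefficients from bumping
    the ceiling when the extrapolation lands exactly on an integer.
    """
    return math.ceil((math.log10(p) - b) / a - 1e-9)


def fit_tail(clusters: list[Cluster], top_frac: float = 0.10, p: float = 0.001,
             min_size: int = 2, mirna_id: str = "") -> TailFit:
    """Fit the size distribution of the top-fraction largest clusters.

    Selects the ceil(top_frac * N) largest clusters (size >= min_size;
    boundary ties all included), histograms their sizes and regresses
    log10(count) on size by ordinary least squares.  Fewer than two distinct
    sizes, or a non-negative slope, yields an invalid (NoCutoff) fit.
    """
    sizes = sorted((c.size for c in clusters if c.size >= min_size), reverse=True)
    no_fit = TailFit(mirna_id, None, None, None, p, 0, top_frac)
    if not sizes:
        return no_fit
    k = math.ceil(top_frac * len(sizes))
    boundary = sizes[k - 1]
    selected = [s for s in sizes if s >= boundary]  # ties at the boundary included
    hist = Counter(selected)
    if len(hist) < 2:
        return dataclasses.replace(no_fit, n_clusters_fit=len(selected))
    xs = np.array(sorted(hist))
    ys = np.log10([hist[x] for x in xs])
    a, b = np.polyfit(xs, ys, 1)
    if a >= 0:
        return no_fit
    return TailFit(
        mirna_id=mirna_id,
        a=float(a),
        b=float(b),
        x_cutoff=cutoff_from_fit(a, b, p),
        p=p,
        n_clusters_fit=len(selected),
        top_frac=top_frac,
    )


def significant_clusters(real_clusters: list[Cluster], fit: TailFit) -> list[Cluster]:
    """Real clusters with size >= x_cutoff, order preserved."""
    if not fit.valid:
        warnings.warn(
            f"no significance cutoff for {fit.mirna_id or 'miRNA'}; returning no clusters",
            stacklevel=2,
        )
        return []
    return [c for c in real_clusters if c.size >= fit.x_cutoff]
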