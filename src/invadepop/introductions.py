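"""Locating and ordering introduction sites from rare-variant geography.

The logic rests on the founder-effect signature of recency: the most recent
introduction has lost the least rare variation, so its origin carries the
densest concentration of rare variants (minor allele frequency below 10% by
default). The pipeline is:

1. flag rare variants on the current genotype matrix;
2. tabulate, per sampling site, the fraction of assessed loci whose minor
   allele segregates among the site's samples ("rare-variant density");
3. interpolate the density over the invaded area by ordinary kriging and
   summarize its decay with great-circle distance from the peak site by
   local regression;
4. peel: remove the peak site's cluster (its samples, and every locus whose
   minor allele is private to that cluster) and repeat on what remains.

Rounds are therefore ordered most-recent-introduction-first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .kriging import KrigingSurface, haversine_km, ordinary_kriging
from .matrix import GenotypeMatrix
from .popgen import allele_frequencies, flag_rare_variants, private_alleles

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- densities
def site_rare_variant_density(
    g: GenotypeMatrix, metadata: pd.DataFrame, rare_flags: np.ndarray
) -> pd.DataFrame:
    """Per-site rare-variant counts and densities.

    A rare variant *segregates at a site* iff at least one copy of its minor
    allele (defined from the whole current matrix) is observed among the
    site's non-missing calls. Density = segregating rare count / number of
    loci with >=1 non-missing call at the site, so sites with different
    missingness are comparable. Sites with zero called loci are flagged and
    excluded (they cannot enter the kriging).

    ``metadata`` must carry sample/site/lat/lon rows for every sample in
    ``g``; site coordinates are the mean of the site's sample coordinates.
    """
    rare_flags = np.asarray(rare_flags, bool)
    if rare_flags.shape != (g.n_loci,):
        raise ValueError("rare_flags must align with the matrix loci")
    meta = metadata.set_index("sample")
    missing_meta = [s for s in g.samples if s not in meta.index]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta[:5]}")
    meta = meta.loc[g.samples]

    freqs = allele_frequencies(g)
    minor_is_alt = freqs.p <= 0.5  # ties cannot be rare, tie-break immaterial
    called = g.called
    rows = []
    for site, sub in meta.groupby("site", sort=True):
        idx = g.sample_index(sub.index)
        sub_calls = g.calls[idx, :]
        sub_called = called[idx, :]
        assessed = sub_called.any(axis=0)
        n_assessed = int(assessed.sum())
        if n_assessed == 0:
            logger.warning("site %s has zero non-missing calls; excluded", site)
            continue
        minor_seen = np.where(
            minor_is_alt,
            ((sub_calls >= 1) & sub_called).any(axis=0),
            ((sub_calls <= 1) & sub_called).any(axis=0),
        )
        count = int((rare_flags & assessed & minor_seen).sum())
        rows.append({
            "site": site,
            "lat": float(sub["lat"].mean()),
            "lon": float(sub["lon"].mean()),
            "n_samples": len(idx),
            "n_rare_segregating": count,
            "n_loci_assessed": n_assessed,
            "density": count / n_assessed,
        })
    return pd.DataFrame(rows)


def peak_site(density: pd.DataFrame) -> pd.Series:
    """Site of maximum rare-variant density; ties break to the
    lexicographically smallest site name."""
    if len(density) == 0:
        raise ValueError("empty density table")
    best = density.sort_values(["density", "site"],
                               ascending=[False, True]).iloc[0]
    return best


# ------------------------------------------------------------ distance decay
@dataclass
class DistanceDecayFit:
    """Local-regression fit of rare-variant density against distance from an
    origin, with a Spearman rank correlation as a monotonicity summary."""

    origin_lat: float
    origin_lon: float
    distances_km: np.ndarray
    densities: np.ndarray
    fitted: np.ndarray
    span: float
    spearman_rho: float
    spearman_p: float


def distance_decay(
    density: pd.DataFrame,
    origin: tuple[float, float],
    span: float = 0.75,
) -> DistanceDecayFit:
    """LOWESS (tricube-weighted local linear regression) of density on
    great-circle distance from ``origin``."""
    if len(density) < 5:
        raise ValueError("distance decay requires at least 5 sites")
    d = haversine_km(density["lat"].to_numpy(), density["lon"].to_numpy(),
                     origin[0], origin[1])
    if np.allclose(d, d[0]):
        raise ValueError("all sites at identical distance from the origin")
    y = density["density"].to_numpy(float)
    fitted = lowess(y, d, frac=span, return_sorted=False)
    if np.allclose(y, y[0]):
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(d, y)
    return DistanceDecayFit(
        origin_lat=float(origin[0]), origin_lon=float(origin[1]),
        distances_km=d, densities=y, fitted=fitted, span=span,
        spearman_rho=float(rho), spearman_p=float(p),
    )


# ------------------------------------------------------------------- peeling
@dataclass
class PeelingRound:
    round_index: int
    focal_cluster: str
    peak_site: str
    peak_lat: float
    peak_lon: float
    density: pd.DataFrame = field(repr=False)
    decay: DistanceDecayFit | None = field(default=None, repr=False)
    surface: KrigingSurface | None = field(default=None, repr=False)
    removed_loci: list[str] = field(default_factory=list, repr=False)
    n_rare: int = 0


@dataclass
class IntroductionInference:
    """Ordered rounds, most-recent introduction first."""

    rounds: list[PeelingRound]
    stop_reason: str

    def origin_sites(self) -> list[str]:
        return [r.peak_site for r in self.rounds]


def iterative_peeling(
    g: GenotypeMatrix,
    metadata: pd.DataFrame,
    cluster_assignment,
    max_rounds: int | None = None,
    rare_threshold: float = 0.10,
    removal: str = "private",
    compute_decay: bool = True,
    compute_surface: bool = False,
) -> IntroductionInference:
    """Identify introduction origins by iterative rare-variant peeling.

    Each round flags rare variants on the current matrix, finds the site with
    the highest rare-variant density, records the majority cluster among that
    site's samples as the focal (most recent remaining) introduction, then
    removes the focal cluster's samples together with loci to be peeled:

    * ``removal="private"`` (default): loci whose minor allele is private to
      the focal cluster;
    * ``removal="segregating"``: every rare locus whose minor allele
      segregates in the focal cluster.

    Recursion continues until one cluster remains, ``max_rounds`` is reached,
    a round finds no rare variants, or a round would remove no loci.
    """
    if removal not in ("private", "segregating"):
        raise ValueError("removal must be 'private' or 'segregating'")
    labels = np.asarray(cluster_assignment, dtype=object)
    if labels.shape != (g.n_samples,):
        raise ValueError("need one cluster label per sample")
    meta_site = metadata.set_index("sample")["site"]

    current = g
    cur_labels = labels
    rounds: list[PeelingRound] = []
    stop_reason = "max_rounds reached"
    n_max = max_rounds if max_rounds is not None else len(set(labels.tolist()))
    for round_index in range(n_max):
        freqs = allele_frequencies(current)
        rare = flag_rare_variants(freqs, threshold=rare_threshold)
        n_rare = int(rare.sum())
        if n_rare == 0:
            stop_reason = "no rare variants remaining"
            logger.info("peeling stopped at round %d: %s", round_index, stop_reason)
            break
        density = site_rare_variant_density(current, metadata, rare)
        best = peak_site(density)
        peak_samples = [s for s in current.samples
                        if meta_site.get(s) == best["site"]]
        idx = current.sample_index(peak_samples)
        peak_labels = cur_labels[idx]
        vals, counts = np.unique(peak_labels.astype(str), return_counts=True)
        focal = sorted(vals[counts == counts.max()])[0]

        decay = None
        if compute_decay and len(density) >= 5:
            try:
                decay = distance_decay(density, (best["lat"], best["lon"]))
            except ValueError as exc:
                logger.warning("distance decay unavailable this round: %s", exc)
        surface = None
        if compute_surface and len(density) >= 3:
            try:
                surface = ordinary_kriging(density["lat"], density["lon"],
                                           density["density"])
            except ValueError as exc:
                logger.warning("kriging unavailable this round: %s", exc)

        # loci to peel
        in_focal = cur_labels.astype(str) == focal
        minor_is_alt = freqs.p <= 0.5
        called = current.called
        sub_calls = current.calls[in_focal, :]
        sub_called = called[in_focal, :]
        oth_calls = current.calls[~in_focal, :]
        oth_called = called[~in_focal, :]

        def _minor_seen(calls_, called_):
            return np.where(
                minor_is_alt,
                ((calls_ >= 1) & called_).any(axis=0),
                ((calls_ <= 1) & called_).any(axis=0),
            )

        seen_focal = _minor_seen(sub_calls, sub_called)
        if removal == "private":
            seen_other = (_minor_seen(oth_calls, oth_called)
                          if (~in_focal).any()
                          else np.zeros(current.n_loci, bool))
            to_remove = seen_focal & ~seen_other
        else:
            to_remove = rare & seen_focal
        removed_loci = [current.loci[j] for j in np.flatnonzero(to_remove)]

        rounds.append(PeelingRound(
            round_index=round_index, focal_cluster=str(focal),
            peak_site=str(best["site"]), peak_lat=float(best["lat"]),
            peak_lon=float(best["lon"]), density=density, decay=decay,
            surface=surface, removed_loci=removed_loci, n_rare=n_rare,
        ))

        keep_samples = ~in_focal
        if not keep_samples.any():
            stop_reason = "all clusters peeled"
            break
        if not removed_loci:
            stop_reason = "round removed no loci"
            logger.info("peeling stopped: %s", stop_reason)
            break
        keep_loci = ~to_remove
        if not keep_loci.any():
            stop_reason = "all loci peeled"
            break
        current = current.take_samples(keep_samples).take_loci(keep_loci)
        cur_labels = cur_labels[keep_samples]
    return IntroductionInference(rounds=rounds, stop_reason=stop_reason)
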