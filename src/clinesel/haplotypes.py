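"""Extended haplotype homozygosity (EHH) and integrated haplotype score (iHS).

EHH at a site x, for chromosomes carrying a given allele at a core site,
is the probability that two randomly chosen carrier chromosomes are
identical over the whole stretch from the core out to x.  It starts at 1
at the core and decays outward as recombination (ancient or recent)
breaks up the carrier haplotypes.  Integrating EHH over genetic distance
for the ancestral and derived allele classes separately gives iHH_A and
iHH_D; their log ratio ln(iHH_A / iHH_D) is the unstandardized iHS.  A
strongly negative iHS means unusually long derived-allele haplotypes —
the classic footprint of recent positive selection on the derived allele.
Raw iHS depends on allele frequency, so values are standardized within
derived-allele-frequency bins before ranking a focal site against a
chromosome-wide background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypePanel",
    "EhhCurve",
    "IhsRecord",
    "ehh",
    "ehh_decay_distance",
    "integrated_ehh",
    "unstandardized_ihs",
    "ihs_scan",
    "standardize_ihs",
    "ihs_percentile",
]

ANCESTRAL = 0
DERIVED = 1

#: adjacent-site physical gaps larger than this are flagged on EHH curves
LARGE_GAP_BP = 200_000


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes: one row per chromosome, one column per site.

    Alleles are coded 0 = ancestral, 1 = derived.  Physical positions are
    1-based bp and must be strictly increasing; genetic positions are cM and
    must be non-decreasing.
    """

    alleles: np.ndarray          # (n_haplotypes, n_sites) values in {0, 1}
    positions_bp: np.ndarray     # (n_sites,) int
    positions_cm: np.ndarray     # (n_sites,) float
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotype x site)")
        n_sites = self.alleles.shape[1]
        if self.positions_bp.shape != (n_sites,) or self.positions_cm.shape != (n_sites,):
            raise ValueError("positions must have one entry per site")
        if n_sites > 1 and not np.all(np.diff(self.positions_bp) > 0):
            raise ValueError("physical positions must be strictly increasing")
        if n_sites > 1 and not np.all(np.diff(self.positions_cm) >= -1e-12):
            raise ValueError("genetic positions must be non-decreasing")
        if not self.site_ids:
            self.site_ids = [f"site{i}" for i in range(n_sites)]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_frequency(self, site: int) -> float:
        return float(self.alleles[:, site].mean())

    def maf(self, site: int) -> float:
        f = self.derived_frequency(site)
        return min(f, 1.0 - f)


@dataclass
class EhhCurve:
    """EHH values outward from a core site, one list per direction.

    Each direction holds parallel arrays over successive sites moving away
    from the core; the core itself (EHH = 1 at distance 0) is included as
    the first entry of both directions so the curve always starts at 1.
    """

    core_site: int
    core_allele: int
    n_carriers: int
    # per direction: site indices, |distance| bp, |distance| cM, EHH values
    left: dict[str, np.ndarray] = field(default_factory=dict)
    right: dict[str, np.ndarray] = field(default_factory=dict)
    large_gap_sites: list[int] = field(default_factory=list)

    def direction(self, which: str) -> dict[str, np.ndarray]:
        if which not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        return getattr(self, which)


def _walk_numpy(alleles, carriers, core, step, stop_below):
    n_c = carriers.size
    denom = n_c * (n_c - 1) / 2.0
    ids = np.zeros(n_c, dtype=np.int64)
    sites = [core]
    values = [1.0]
    j = core + step
    n_sites = alleles.shape[1]
    while 0 <= j < n_sites:
        ids = ids * 2 + alleles[carriers, j]
        # compress labels so they never overflow and group counts are easy
        _, ids, counts = np.unique(ids, return_inverse=True, return_counts=True)
        val = float(np.sum(counts * (counts - 1)) / 2.0 / denom)
        sites.append(j)
        values.append(val)
        if val < stop_below:
            break
        j += step
    return np.asarray(sites), np.asarray(values)


try:  # numba accelerates the partition-refinement walk ~50x; numpy fallback kept
    from numba import njit

    @njit(cache=True)
    def _walk_numba(alleles, carriers, core, step, stop_below):  # pragma: no cover
        n_c = carriers.size
        n_sites = alleles.shape[1]
        denom = n_c * (n_c - 1) / 2.0
        ids = np.zeros(n_c, dtype=np.int64)
        sites = np.empty(n_sites + 1, dtype=np.int64)
        values = np.empty(n_sites + 1, dtype=np.float64)
        sites[0] = core
        values[0] = 1.0
        m = 1
        n_groups = 1
        j = core + step
        while 0 <= j < n_sites:
            cnt = np.zeros(2 * n_groups, dtype=np.int64)
            newid = np.empty(n_c, dtype=np.int64)
            for t in range(n_c):
                k = ids[t] * 2 + alleles[carriers[t], j]
                newid[t] = k
                cnt[k] += 1
            remap = np.empty(2 * n_groups, dtype=np.int64)
            g = 0
            s = 0.0
            for k in range(2 * n_groups):
                if cnt[k] > 0:
                    remap[k] = g
                    g += 1
                    s += cnt[k] * (cnt[k] - 1) / 2.0
            for t in range(n_c):
                ids[t] = remap[newid[t]]
            n_groups = g
            val = s / denom
            sites[m] = j
            values[m] = val
            m += 1
            if val < stop_below:
                break
            j += step
        return sites[:m], values[:m]

    def _ehh_one_direction(alleles, carriers, core, step, stop_below):
        return _walk_numba(
            np.ascontiguousarray(alleles), carriers.astype(np.int64),
            core, step, stop_below,
        )

except ImportError:  # pragma: no cover
    _ehh_one_direction = _walk_numpy


def ehh(
    panel: HaplotypePanel,
    core_site: int,
    core_allele: int,
    stop_below: float = 0.0,
) -> EhhCurve:
    """EHH curve for one allele class at a core site, both directions.

    ``stop_below`` truncates the outward walk once EHH drops under the given
    value (the first sub-threshold site is still recorded, so downstream
    decay/integration logic can see the crossing).  The default 0.0 walks
    until EHH is exactly zero or the panel edge is reached.
    """
    allele_col = panel.alleles[:, core_site]
    carriers = np.flatnonzero(allele_col == core_allele)
    if carriers.size < 2:
        raise ValueError(
            f"EHH undefined: only {carriers.size} haplotype(s) carry allele "
            f"{core_allele} at site {core_site}"
        )
    curve = EhhCurve(core_site=core_site, core_allele=core_allele, n_carriers=carriers.size)
    for name, step in (("left", -1), ("right", +1)):
        sites, values = _ehh_one_direction(panel.alleles, carriers, core_site, step, stop_below)
        d_bp = np.abs(panel.positions_bp[sites] - panel.positions_bp[core_site])
        d_cm = np.abs(panel.positions_cm[sites] - panel.positions_cm[core_site])
        getattr(curve, name).update(
            sites=sites, distance_bp=d_bp, distance_cm=d_cm, ehh=values
        )
    gaps = np.diff(panel.positions_bp)
    curve.large_gap_sites = [int(i) for i in np.flatnonzero(gaps > LARGE_GAP_BP)]
    return curve


def ehh_decay_distance(
    curve: EhhCurve, threshold: float = 0.05
) -> dict[str, tuple[float, bool]]:
    """Distance (bp) from the core to the most distant site with EHH >= threshold.

    Returns ``{"left": (bp, censored), "right": (bp, censored)}``; censored is
    True when the curve never dropped below the threshold before the panel
    edge, in which case the edge distance is reported.
    """
    out: dict[str, tuple[float, bool]] = {}
    for name in ("left", "right"):
        d = curve.direction(name)
        vals, dist = d["ehh"], d["distance_bp"]
        keep = vals >= threshold
        censored = bool(keep[-1])  # still above threshold at the last computed site
        dist_at = float(dist[keep][-1]) if keep.any() else 0.0
        out[name] = (dist_at, censored)
    return out


def integrated_ehh(curve: EhhCurve, threshold: float = 0.05) -> float:
    """iHH: trapezoidal integral of EHH over genetic distance (cM).

    Each direction is truncated at the last site with EHH >= threshold (no
    interpolation past it); the two directional integrals are summed.
    """
    total = 0.0
    any_span = False
    for name in ("left", "right"):
        d = curve.direction(name)
        vals, dist = d["ehh"], d["distance_cm"]
        keep = vals >= threshold
        if keep.sum() < 2:
            continue
        last = np.flatnonzero(keep)[-1]
        total += float(np.trapezoid(vals[: last + 1], dist[: last + 1]))
        any_span = True
    if not any_span:
        warnings.warn("EHH below threshold immediately in both directions; iHH = 0")
    return total


@dataclass
class IhsRecord:
    site: int
    site_id: str
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    ihs_unstd: float | None
    ihs_std: float | None = None
    freq_bin: int | None = None


def unstandardized_ihs(
    panel: HaplotypePanel,
    core_site: int,
    threshold: float = 0.05,
    maf_min: float = 0.05,
) -> IhsRecord:
    """ln(iHH_ancestral / iHH_derived) at one site.

    Long derived-allele haplotypes give iHH_D > iHH_A and hence a negative
    value.  Sites below the MAF floor are rejected; a zero iHH on either side
    leaves the ratio undefined (ihs_unstd = None).
    """
    if panel.maf(core_site) < maf_min - 1e-12:
        raise ValueError(
            f"site {core_site} has MAF {panel.maf(core_site):.4f} < {maf_min}"
        )
    ihh = {}
    for allele in (ANCESTRAL, DERIVED):
        curve = ehh(panel, core_site, allele, stop_below=threshold)
        ihh[allele] = integrated_ehh(curve, threshold=threshold)
    value = None
    if ihh[ANCESTRAL] > 0 and ihh[DERIVED] > 0:
        value = float(np.log(ihh[ANCESTRAL] / ihh[DERIVED]))
    return IhsRecord(
        site=core_site,
        site_id=panel.site_ids[core_site],
        derived_freq=panel.derived_frequency(core_site),
        ihh_ancestral=ihh[ANCESTRAL],
        ihh_derived=ihh[DERIVED],
        ihs_unstd=value,
    )


def ihs_scan(
    panel: HaplotypePanel,
    threshold: float = 0.05,
    maf_min: float = 0.05,
    sites: np.ndarray | None = None,
) -> list[IhsRecord]:
    """Unstandardized iHS at every panel site passing the MAF filter
    (or at an explicit site subset)."""
    if sites is None:
        sites = np.arange(panel.n_sites)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in sites:
            s = int(s)
            if panel.maf(s) < maf_min - 1e-12:
                continue
            col = panel.alleles[:, s]
            if (col == ANCESTRAL).sum() < 2 or (col == DERIVED).sum() < 2:
                continue
            records.append(unstandardized_ihs(panel, s, threshold, maf_min))
    return records


def standardize_ihs(
    records: list[IhsRecord],
    n_bins: int = 50,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> list[IhsRecord]:
    """Standardize iHS within equal-width derived-allele-frequency bins.

    Within each bin, standardized = (value - bin mean) / bin sample SD
    (denominator n - 1).  Bins with fewer than two defined values, or zero
    SD, yield missing standardized values.  Records are modified in place
    and returned.
    """
    if not records:
        raise ValueError("no iHS records to standardize")
    lo, hi = freq_range
    edges = np.linspace(lo, hi, n_bins + 1)
    freqs = np.array([r.derived_freq for r in records])
    bins = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, n_bins - 1)
    for r, b in zip(records, bins):
        r.freq_bin = int(b)
    for b in range(n_bins):
        members = [r for r, rb in zip(records, bins) if rb == b and r.ihs_unstd is not None]
        if len(members) < 2:
            for r in members:
                r.ihs_std = None
            continue
        vals = np.array([r.ihs_unstd for r in members])
        mu, sd = vals.mean(), vals.std(ddof=1)
        for r in members:
            r.ihs_std = None if sd == 0 else float((r.ihs_unstd - mu) / sd)
    return records


def ihs_percentile(focal_ihs: float, background: np.ndarray) -> float:
    """Percentile rank of |focal iHS| among |background| values.

    100 x (# background with magnitude strictly less than the focal
    magnitude) / (# background); extreme negative iHS therefore ranks high.
    """
    if focal_ihs is None or (isinstance(focal_ihs, float) and np.isnan(focal_ihs)):
        raise ValueError("focal iHS is missing")
    background = np.asarray(background, dtype=float)
    background = background[~np.isnan(background)]
    if background.size == 0:
        raise ValueError("background is empty")
    return float(100.0 * np.mean(np.abs(background) < abs(focal_ihs)))
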