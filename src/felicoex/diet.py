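"""Scat-diet composition and trophic-niche statistics.

Composition metrics per predator:

- **FO** — frequency of occurrence, the percentage of scats containing a prey
  category (columns can sum past 100 when scats hold several items).
- **CFO** — corrected FO: each scat distributes weight 1 equally over its
  items, so CFO sums to 100 over categories.
- **RBC** — relative biomass consumed: CFO weighted by the modeled biomass a
  predator ingests per collectable scat, ``y = a − b·exp(−c·x)`` with
  ``x = prey mass / predator mass`` (an asymptotic regression for obligate
  carnivores; constants configurable).

Niche statistics: Levins standardized breadth, Pianka overlap (defaulting to
FO-derived proportion vectors), and Brillouin diversity with bootstrapped
scat-accumulation curves for sampling adequacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln

#: Default constants of the asymptotic biomass-per-scat regression.
BIOMASS_CONSTANTS = {"a": 0.033, "b": 0.025, "c": 4.284}

#: Predator average adult body masses (kg).
PREDATOR_ABM = {"leopard": 43.0, "golden_cat": 9.0}

SIZE_CLASS_ORDER = ("large", "medium", "small", "very_small")
GROUP_ORDER = ("ungulates", "primates", "carnivores", "rodents", "birds")


def size_class(abm_kg: float) -> str:
    """Prey body-size class from average adult body mass.

    Boundaries: very small ≤ 2 kg < small < 10 kg ≤ medium < 30 kg ≤ large.
    """
    if abm_kg <= 0:
        raise ValueError("ABM must be positive")
    if abm_kg <= 2:
        return "very_small"
    if abm_kg < 10:
        return "small"
    if abm_kg < 30:
        return "medium"
    return "large"


def load_prey_traits() -> pd.DataFrame:
    """Packaged prey trait table: taxon, ABM (kg), taxonomic group."""
    with resources.files("felicoex.data").joinpath("prey_traits.csv").open() as fh:
        traits = pd.read_csv(fh)
    traits["size_class"] = [size_class(m) for m in traits["abm_kg"]]
    return traits


def load_scat_reconstruction(predator: str) -> pd.DataFrame:
    """Packaged synthetic scat tables reconstructed from published per-taxon
    summary columns (one row per prey item: scat_id, predator, prey_taxon).

    These are stand-ins for the study's non-public raw scat data: the leopard
    table (9 scats, 11 items) is the unique composition consistent with its
    printed FO/CFO columns; the golden-cat table (16 scats, 22 items, one scat
    holding two Murinae items) matches every printed FO/CFO cell at 1 d.p.
    """
    name = {"leopard": "leopard_scats_reconstructed.csv",
            "golden_cat": "goldencat_scats_reconstructed.csv"}[predator]
    with resources.files("felicoex.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_published_diet_table() -> pd.DataFrame:
    """Published per-taxon diet summary (FO/CFO/RBC columns per predator)."""
    with resources.files("felicoex.data").joinpath("published_diet_table.csv").open() as fh:
        return pd.read_csv(fh)


def _check_scats(scats: pd.DataFrame, traits: pd.DataFrame | None = None) -> None:
    if scats.empty:
        raise ValueError("scat table is empty")
    for col in ("scat_id", "prey_taxon"):
        if col not in scats.columns:
            raise ValueError(f"scat table missing column {col!r}")
    if traits is not None:
        unknown = sorted(set(scats["prey_taxon"]) - set(traits["taxon"]))
        if unknown:
            raise ValueError(f"prey taxa missing from trait table: {unknown}")


def fo(scats: pd.DataFrame) -> pd.Series:
    """Frequency of occurrence (%) per prey taxon."""
    _check_scats(scats)
    n_scats = scats["scat_id"].nunique()
    present = scats.drop_duplicates(["scat_id", "prey_taxon"])
    counts = present.groupby("prey_taxon").size()
    return 100.0 * counts / n_scats


def cfo(scats: pd.DataFrame) -> pd.Series:
    """Corrected frequency of occurrence (%) per prey taxon.

    Each scat's unit weight is split equally over its items (items of the same
    taxon in one scat each carry their share).
    """
    _check_scats(scats)
    n_scats = scats["scat_id"].nunique()
    items_per_scat = scats.groupby("scat_id").size()
    w = 1.0 / items_per_scat.loc[scats["scat_id"]].to_numpy()
    weights = pd.Series(w, index=scats.index).groupby(scats["prey_taxon"]).sum()
    return 100.0 * weights / n_scats


def biomass_per_scat(
    prey_abm: float | np.ndarray,
    predator_abm: float,
    constants: dict | None = None,
) -> float | np.ndarray:
    """Biomass ingested per collectable scat, in predator-mass units.

    ``y = a − b·exp(−c·x)`` with ``x = prey_abm / predator_abm``; y rises from
    ``a − b`` at x = 0 to the asymptote ``a`` for prey much larger than the
    predator.
    """
    if predator_abm <= 0:
        raise ValueError("predator ABM must be positive")
    k = dict(BIOMASS_CONSTANTS, **(constants or {}))
    x = np.asarray(prey_abm, dtype=float) / predator_abm
    y = k["a"] - k["b"] * np.exp(-k["c"] * x)
    return float(y) if np.isscalar(prey_abm) else y


def rbc(
    cfo_pct: pd.Series,
    traits: pd.DataFrame,
    predator_abm: float,
    constants: dict | None = None,
) -> pd.Series:
    """Relative biomass consumed (%) per taxon from CFO and prey masses."""
    abm = traits.set_index("taxon")["abm_kg"]
    missing = [t for t in cfo_pct.index if t not in abm.index or not np.isfinite(abm[t])]
    if missing:
        raise ValueError(f"missing ABM for taxa: {missing}")
    y = biomass_per_scat(abm.loc[cfo_pct.index].to_numpy(), predator_abm, constants)
    w = cfo_pct.to_numpy() * y
    return pd.Series(100.0 * w / w.sum(), index=cfo_pct.index)


def levins_standardized(p: np.ndarray, n_categories: int) -> float:
    """Levins standardized niche breadth B_A = (1/Σp² − 1)/(n − 1) ∈ [0, 1]."""
    if n_categories < 2:
        raise ValueError("need at least two categories")
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    b = 1.0 / np.sum(p**2)
    return float((b - 1.0) / (n_categories - 1.0))


def pianka(p1: pd.Series, p2: pd.Series) -> float:
    """Pianka's symmetric niche overlap on union-aligned proportion vectors.

    Inputs are per-taxon proportions each summing to 1; taxa absent from one
    predator enter as explicit zeros via the index union.
    """
    for p in (p1, p2):
        if not np.isclose(float(p.sum()), 1.0):
            raise ValueError("each proportion vector must sum to 1")
    union = p1.index.union(p2.index)
    a = p1.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    b = p2.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


def brillouin(counts: np.ndarray) -> float:
    """Brillouin diversity HB = (ln N! − Σ ln n_i!) / N via log-gamma."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one item")
    return float((gammaln(n + 1) - gammaln(counts + 1).sum()) / n)


def accumulation_curve(
    scats: pd.DataFrame,
    iterations: int = 10_000,
    seed: int | None = None,
    adequacy_pct: float = 1.0,
) -> pd.DataFrame:
    """Bootstrapped Brillouin accumulation curve over scat sample size.

    For k = 1..n scats, draws ``iterations`` resamples of k scats with
    replacement, pools their per-taxon item counts, and records the mean HB.
    ``incremental_pct`` is the percent change from k−1 to k; the final value
    below ``adequacy_pct`` flags adequate sampling effort.  The returned frame
    carries the flag in ``df.attrs["adequate"]``.
    """
    _check_scats(scats)
    ids = scats["scat_id"].unique()
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two scats")
    taxa = pd.Index(scats["prey_taxon"].unique())
    # scat × taxon item-count matrix
    mat = (
        scats.groupby(["scat_id", "prey_taxon"]).size().unstack(fill_value=0)
        .reindex(index=ids, columns=taxa, fill_value=0)
        .to_numpy()
    )
    rng = np.random.default_rng(seed)
    mean_hb = np.empty(n)
    for k in range(1, n + 1):
        picks = rng.integers(0, n, size=(iterations, k))
        pooled = mat[picks].sum(axis=1)  # iterations × taxa
        ntot = pooled.sum(axis=1)
        hb = (gammaln(ntot + 1) - gammaln(pooled + 1).sum(axis=1)) / ntot
        mean_hb[k - 1] = hb.mean()
    inc = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        prev = mean_hb[:-1]
        inc[1:] = np.where(prev > 0, 100.0 * (mean_hb[1:] - prev) / prev, 0.0)
    out = pd.DataFrame({"k": np.arange(1, n + 1), "mean_hb": mean_hb, "incremental_pct": inc})
    final_inc = inc[-1] if n > 1 else 0.0
    out.attrs["adequate"] = bool(abs(final_inc) < adequacy_pct)
    return out


@dataclass
class DietProfile:
    """Per-predator diet composition with group and size-class aggregates."""

    predator: str
    taxa: pd.DataFrame  # taxon, group, size_class, abm_kg, fo, cfo, rbc
    n_scats: int
    n_items: int
    groups: pd.DataFrame = field(default=None)
    size_classes: pd.DataFrame = field(default=None)

    @property
    def mean_items_per_scat(self) -> float:
        return self.n_items / self.n_scats

    def proportions(self, basis: str = "fo") -> pd.Series:
        """Per-taxon proportion vector (summing to 1) on the given basis."""
        col = self.taxa.set_index("taxon")[basis]
        return col / col.sum()


def _aggregate_by(scats: pd.DataFrame, taxa_df: pd.DataFrame, key: str, order) -> pd.DataFrame:
    n_scats = scats["scat_id"].nunique()
    member = taxa_df.set_index("taxon")[key]
    with_key = scats.assign(_k=member.loc[scats["prey_taxon"]].to_numpy())
    # FO of a group: share of scats containing >=1 member taxon (not a sum)
    fo_g = with_key.drop_duplicates(["scat_id", "_k"]).groupby("_k").size() * 100.0 / n_scats
    sums = taxa_df.groupby(key)[["cfo", "rbc"]].sum()
    out = pd.DataFrame({"fo": fo_g}).join(sums, how="outer").fillna(0.0)
    out = out.reindex([g for g in order if g in out.index])
    out.index.name = key
    return out.reset_index()


def aggregate(profile: DietProfile, scats: pd.DataFrame, by: str) -> pd.DataFrame:
    """Aggregate a profile's FO/CFO/RBC by ``group`` or ``size_class``."""
    order = GROUP_ORDER if by == "group" else SIZE_CLASS_ORDER
    return _aggregate_by(scats, profile.taxa, by, order)


def diet_profile(
    scats: pd.DataFrame,
    traits: pd.DataFrame,
    predator: str,
    predator_abm: float | None = None,
    constants: dict | None = None,
) -> DietProfile:
    """Full per-predator diet profile: FO, CFO, RBC plus aggregates."""
    _check_scats(scats, traits)
    if predator_abm is None:
        predator_abm = PREDATOR_ABM[predator]
    fo_s, cfo_s = fo(scats), cfo(scats)
    rbc_s = rbc(cfo_s, traits, predator_abm, constants)
    tr = traits.set_index("taxon")
    taxa_df = pd.DataFrame(
        {
            "taxon": fo_s.index,
            "group": tr.loc[fo_s.index, "group"].to_numpy(),
            "size_class": [size_class(m) for m in tr.loc[fo_s.index, "abm_kg"]],
            "abm_kg": tr.loc[fo_s.index, "abm_kg"].to_numpy(),
            "fo": fo_s.to_numpy(),
            "cfo": cfo_s.to_numpy(),
            "rbc": rbc_s.to_numpy(),
        }
    ).reset_index(drop=True)
    prof = DietProfile(
        predator=predator,
        taxa=taxa_df,
        n_scats=scats["scat_id"].nunique(),
        n_items=len(scats),
    )
    prof.groups = _aggregate_by(scats, taxa_df, "group", GROUP_ORDER)
    prof.size_classes = _aggregate_by(scats, taxa_df, "size_class", SIZE_CLASS_ORDER)
    return prof
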