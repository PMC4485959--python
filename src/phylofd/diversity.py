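"""Per-plot functional and phylogenetic diversity indices.

Three richness-independent community descriptors, weighted where relevant
by species basal area (m²/ha):

* **FDis** — functional dispersion: the abundance-weighted mean Euclidean
  distance of species to the abundance-weighted centroid in standardized
  trait space.
* **PSV** — phylogenetic species variability: one minus the mean
  phylogenetic correlation among the species present (1 on a star
  phylogeny, smaller when co-occurring species are close relatives).
* **CWM** — community-weighted mean of a trait (the functional-identity
  axis; here typically leaf nitrogen content).

By convention, a monoculture plot carries FDis = 0 and PSV = 0: with a
single species there is no functional or phylogenetic spread to measure.
Trait standardization is computed once over the full species pool so that
plot values are comparable across the landscape.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .treeio import LabelMismatchError, Phylogeny, phylo_vcv, vcv_to_correlation

__all__ = [
    "standardize_traits",
    "fdis",
    "psv",
    "cwm",
    "diversity_profile",
    "read_trait_table",
    "read_community",
]

#: traits entering FDis by default (shade tolerance deliberately excluded)
DEFAULT_FDIS_TRAITS = ("maxH", "Wd", "Sm")
#: traits summarized as community-weighted means by default
DEFAULT_CWM_TRAITS = ("N",)


def standardize_traits(
    table: pd.DataFrame, trait_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Z-score trait columns over the species pool (mean 0, sample SD 1).

    Raises ``ValueError`` naming any requested trait that is missing, has
    missing values, or has zero variance across the pool.
    """
    if trait_names is None:
        trait_names = list(table.columns)
    missing_cols = [t for t in trait_names if t not in table.columns]
    if missing_cols:
        raise ValueError(f"traits not in table: {missing_cols}")
    if len(table) < 2:
        raise ValueError("need at least 2 species to standardize traits")
    sub = table[list(trait_names)].astype(float)
    if sub.isna().any().any():
        bad = sorted(sub.columns[sub.isna().any()])
        raise ValueError(f"missing values in traits: {bad}")
    sd = sub.std(ddof=1)
    flat = sorted(sd.index[sd == 0])
    if flat:
        raise ValueError(f"zero-variance traits: {flat}")
    return (sub - sub.mean()) / sd


def _positive_abundances(abundances: Mapping[str, float] | pd.Series) -> pd.Series:
    a = pd.Series(dict(abundances), dtype=float)
    if (a < 0).any():
        raise ValueError("negative basal area")
    a = a[a > 0]
    if a.empty:
        raise ValueError("plot has no species with positive abundance")
    return a


def fdis(
    abundances: Mapping[str, float] | pd.Series, traits_std: pd.DataFrame
) -> float:
    """Functional dispersion of one plot.

    With relative abundances ``p_i`` and standardized trait vectors
    ``x_i``, the weighted centroid is ``c = sum_i p_i x_i`` and
    ``FDis = sum_i p_i ||x_i - c||``.  Monocultures return 0.
    """
    a = _positive_abundances(abundances)
    missing = [s for s in a.index if s not in traits_std.index]
    if missing:
        raise LabelMismatchError("species missing from trait table", missing)
    if len(a) == 1:
        return 0.0
    X = traits_std.loc[a.index].to_numpy(dtype=float)
    w = a.to_numpy() / a.sum()
    centroid = w @ X
    z = np.linalg.norm(X - centroid, axis=1)
    return float(w @ z)


def psv(plot_species: Iterable[str], C: pd.DataFrame) -> float:
    """Phylogenetic species variability of the species present in a plot.

    For ``n >= 2`` species with phylogenetic correlation submatrix
    ``C_sub``: ``PSV = (n * tr(C_sub) - sum(C_sub)) / (n * (n - 1))``,
    i.e. one minus the mean off-diagonal correlation.  A monoculture
    returns 0 by convention.
    """
    species = list(dict.fromkeys(plot_species))
    if not species:
        raise ValueError("empty species set")
    missing = [s for s in species if s not in C.index]
    if missing:
        raise LabelMismatchError("species missing from phylogeny", missing)
    n = len(species)
    if n == 1:
        return 0.0
    sub = C.loc[species, species].to_numpy(dtype=float)
    return float((n * np.trace(sub) - sub.sum()) / (n * (n - 1)))


def cwm(abundances: Mapping[str, float] | pd.Series, trait: pd.Series) -> float:
    """Basal-area-weighted mean trait value of one plot."""
    a = _positive_abundances(abundances)
    missing = [s for s in a.index if s not in trait.index or pd.isna(trait[s])]
    if missing:
        raise LabelMismatchError("species missing trait value", missing)
    w = a / a.sum()
    return float((w * trait.loc[a.index].astype(float)).sum())


def diversity_profile(
    community: pd.DataFrame,
    traits: pd.DataFrame,
    tree: Phylogeny,
    fdis_traits: Sequence[str] = DEFAULT_FDIS_TRAITS,
    cwm_traits: Sequence[str] = DEFAULT_CWM_TRAITS,
) -> pd.DataFrame:
    """Per-plot richness, FDis, PSV and CWM columns for a community matrix.

    ``community`` is plots x species (wide, basal areas >= 0).  Every
    species appearing in the community must be present in both the trait
    table and the tree; mismatches are a hard error listing offenders.
    Standardization for FDis is over the full pool of community species.
    """
    if (community.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative basal area in community matrix")
    pool = list(community.columns)
    for label_set, context in (
        (traits.index, "species absent from trait table"),
        (tree.tip_labels, "species absent from phylogeny"),
    ):
        missing = [s for s in pool if s not in set(label_set)]
        if missing:
            raise LabelMismatchError(context, missing)

    traits_std = standardize_traits(traits.loc[pool], fdis_traits)
    C = vcv_to_correlation(phylo_vcv(tree)).loc[pool, pool]

    rows = []
    for plot, ab in community.iterrows():
        a = ab[ab > 0]
        if a.empty:
            raise ValueError(f"plot {plot!r} has no species with positive abundance")
        row = {
            "richness": int(len(a)),
            "FDis": fdis(a, traits_std),
            "PSV": psv(a.index, C),
        }
        for t in cwm_traits:
            row[f"CWM_{t}"] = cwm(a, traits[t])
        rows.append(pd.Series(row, name=plot))
    out = pd.DataFrame(rows)
    out["richness"] = out["richness"].astype(int)
    out.index.name = community.index.name or "plot"
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Species x trait CSV; first column is the species identifier."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "species"
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate species in trait table: {dupes}")
    return df


def read_community(path: str | Path) -> pd.DataFrame:
    """Plot x species basal-area matrix from CSV.

    Two dialects are auto-detected from the header: long format with
    columns (plot, species, basal_area), or a wide matrix whose first
    column is the plot identifier and remaining columns are species.
    """
    df = pd.read_csv(path)
    cols = {c.lower() for c in df.columns}
    if {"plot", "species"} <= cols:
        value_col = next(
            (c for c in df.columns if c.lower() in ("basal_area", "abundance", "value")),
            None,
        )
        if value_col is None:
            raise ValueError(
                "long-format community CSV needs a basal_area/abundance column"
            )
        plot_col = next(c for c in df.columns if c.lower() == "plot")
        sp_col = next(c for c in df.columns if c.lower() == "species")
        wide = df.pivot_table(
            index=plot_col, columns=sp_col, values=value_col, aggfunc="sum", fill_value=0.0
        )
        wide.index.name = "plot"
        wide.columns = wide.columns.astype(str)
        wide.columns.name = "species"
        return wide
    wide = df.set_index(df.columns[0])
    wide.index.name = "plot"
    wide.columns = wide.columns.astype(str)
    wide.columns.name = "species"
    return wide.astype(float).fillna(0.0)
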