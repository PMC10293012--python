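"""TCR beta-chain repertoire statistics.

Clonotype identity is the CDR3beta amino-acid junction; V/J calls travel as
annotation only. A "unit" is one patient x compartment repertoire: a mapping
of junction -> duplicate count, from which per-unit frequencies follow.

Implements the repertoire readouts used to characterize clonal expansion in
brain tumors: Chao1 lower-bound richness, five-category clone-size binning,
blood/tumor expansion classes, tumor exclusivity of the most-expanded
clones, Morisita-Horn overlap, and exact matching against an antigen
database (VDJdb-style, score-filtered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AIRR_COLUMNS = ("patient_id", "compartment", "junction_aa", "v_call", "j_call",
                "duplicate_count")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: frequency bins, right-closed: label -> (low, high]
CLONE_SIZE_BINS = {
    "Rare": (0.0, 1e-4),
    "Small": (1e-4, 1e-3),
    "Medium": (1e-3, 1e-2),
    "Large": (1e-2, 1e-1),
    "Hyperexpanded": (1e-1, 1.0),
}


def validate_clonotypes(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(AIRR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"clonotype table missing columns {sorted(missing)}")
    if (table["duplicate_count"] < 1).any():
        raise ValueError("duplicate_count must be >= 1")
    bad = table["junction_aa"].map(lambda s: not set(s) <= set(AA_ALPHABET))
    if bad.any():
        raise ValueError("junction_aa outside the 20-letter amino-acid alphabet")
    return table


def repertoire_units(table: pd.DataFrame):
    """Iterate (patient, compartment, counts-by-junction Series)."""
    for (pat, comp), grp in table.groupby(["patient_id", "compartment"], observed=True):
        counts = grp.groupby("junction_aa", observed=True)["duplicate_count"].sum()
        yield pat, comp, counts


def qc_repertoire(table: pd.DataFrame, min_unique: int = 20) -> pd.DataFrame:
    """Drop patient x compartment units with fewer than ``min_unique``
    distinct clonotypes (strict <)."""
    keep = []
    for pat, comp, counts in repertoire_units(table):
        if counts.size >= min_unique:
            keep.append((pat, comp))
    if not keep:
        return table.iloc[0:0]
    mask = table.set_index(["patient_id", "compartment"]).index.isin(keep)
    return table.loc[mask]


def chao1(counts: pd.Series | np.ndarray) -> float:
    """Bias-corrected Chao1 lower-bound richness estimate.

    S_obs + f1*(f1-1) / (2*(f2+1)) with f1/f2 the numbers of clonotypes seen
    exactly once/twice; well-defined when f2 = 0.
    """
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty repertoire unit")
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def clone_size_categories(counts: pd.Series) -> tuple[pd.Series, pd.Series, float]:
    """Five-category clone-size binning of one unit.

    Returns (per-clonotype category, per-category cell fraction, fraction of
    cells in Large + Hyperexpanded clones — the "substantially expanded"
    readout). Bins are right-closed on within-unit frequency.
    """
    total = counts.sum()
    freq = counts / total
    if ((freq <= 0) | (freq > 1)).any():
        raise ValueError("frequency outside (0, 1]")

    def assign(f: float) -> str:
        for name, (lo, hi) in CLONE_SIZE_BINS.items():
            if lo < f <= hi:
                return name
        raise ValueError(f"frequency {f} not binnable")

    cats = freq.map(assign).rename("category")
    cell_frac = (
        freq.groupby(cats).sum().reindex(CLONE_SIZE_BINS.keys(), fill_value=0.0)
    )
    expanded = float(cell_frac["Large"] + cell_frac["Hyperexpanded"])
    return cats, cell_frac, expanded


EXPANSION_CLASSES = ("not expanded", "tumor-only expanded", "blood-only expanded",
                     "dually expanded")


def expansion_classes(
    blood: pd.Series, tumor: pd.Series, expand_min_count: int = 2
) -> pd.DataFrame:
    """Classify clonotypes by where they are expanded.

    A clonotype counts as expanded in a compartment when its duplicate count
    there is >= expand_min_count; absence means count 0. Returns a table over
    the union of clonotypes with blood/tumor counts and the class label.
    """
    union = blood.index.union(tumor.index)
    b = blood.reindex(union, fill_value=0)
    t = tumor.reindex(union, fill_value=0)
    eb = b >= expand_min_count
    et = t >= expand_min_count
    label = np.select(
        [eb & et, et & ~eb, eb & ~et],
        ["dually expanded", "tumor-only expanded", "blood-only expanded"],
        default="not expanded",
    )
    return pd.DataFrame(
        {"blood_count": b, "tumor_count": t, "class": label}, index=union
    )


def top_expanded_tumor_exclusive(
    blood: pd.Series, tumor: pd.Series, k: int = 15
) -> tuple[float, int]:
    """Proportion of the k most-expanded tumor clonotypes absent from blood.

    Tumor clonotypes are ranked by descending count with lexicographic
    junction tie-break; if fewer than k exist all are used and the actual k
    is returned alongside the proportion.
    """
    if tumor.size == 0:
        raise ValueError("empty tumor unit")
    order = sorted(tumor.index, key=lambda j: (-tumor[j], j))
    top = order[: min(k, len(order))]
    blood_set = set(blood.index[blood > 0])
    absent = sum(1 for j in top if j not in blood_set)
    return absent / len(top), len(top)


def morisita_overlap(u: pd.Series, v: pd.Series) -> float:
    """Morisita-Horn overlap of two repertoire units, in [0, 1].

    2 * sum(p_i * q_i) / (sum(p_i^2) + sum(q_i^2)) over the union of
    clonotypes, with p/q the within-unit frequencies.
    """
    if u.size == 0 or v.size == 0:
        raise ValueError("empty repertoire unit")
    union = u.index.union(v.index)
    p = (u / u.sum()).reindex(union, fill_value=0.0).to_numpy()
    q = (v / v.sum()).reindex(union, fill_value=0.0).to_numpy()
    return float(2.0 * (p * q).sum() / ((p ** 2).sum() + (q ** 2).sum()))


@dataclass
class AntigenDb:
    """Antigen-specificity database: junction -> (species, confidence score)."""

    table: pd.DataFrame  # columns junction_aa, species, score

    def __post_init__(self) -> None:
        if self.table.duplicated(["junction_aa", "species"]).any():
            raise ValueError("duplicate (junction, species) pairs")
        if (self.table["score"] < 0).any():
            raise ValueError("scores must be >= 0")


def match_antigen_db(
    table: pd.DataFrame,
    db: AntigenDb,
    min_score: int = 1,
    group_cols: tuple[str, ...] = ("patient_id", "compartment"),
) -> pd.DataFrame:
    """Exact CDR3beta matches against the antigen database.

    Only database entries with score >= min_score participate. Returns one
    row per unique (group, junction, species) match; counting rows per group
    gives the unique-match readout.
    """
    if db.table.empty:
        raise ValueError("empty antigen database")
    usable = db.table[db.table["score"] >= min_score]
    merged = table.merge(usable, on="junction_aa", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=[*group_cols, "junction_aa", "species", "score"])
    return (
        merged[[*group_cols, "junction_aa", "species", "score"]]
        .drop_duplicates([*group_cols, "junction_aa", "species"])
        .reset_index(drop=True)
    )
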