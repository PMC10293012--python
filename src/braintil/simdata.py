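"""Synthetic multi-modal brain-tumor cohort generator.

Builds a cohort of glioma and brain-metastasis (BrM) patients with a planted
pTRT-high/low ground truth, emitting every modality the analysis pipeline
consumes: single-cell counts with cluster labels, bulk sorted-population
counts (with tumor-cell contamination of the sorted T cell profiles), TCR
beta repertoires with power-law clone sizes and tumor-exclusive expansion in
pTRT-high patients, flow-cytometry event tables with CD39/CCR7 marker
mixtures, and spatial scenes with perivascular-niche-enriched pTRT
placement.

The generator states a world, it does not fit one: per-patient pTRT
fractions are bimodal (low ~5%, high ~45% of CD8+ cells, with the gap
between 15% and 30% essentially unpopulated, as observed in practice), BrM
patients are pTRT-high with probability one half, gliomas never. One global
seed is expanded into per-modality substreams so identical configs give
bit-identical cohorts and modalities can be regenerated independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scio
from scipy import sparse

from .bulkproc import ExpressionMatrix
from .spatial import SpatialScene
from .tcr import AntigenDb, AA_ALPHABET

FLOW_MARKERS = ("CD39", "CCR7", "PD1", "TIM3", "CD103", "CXCL13", "Ki67", "CD45RO")
PTRT_CLUSTER = "C3"
BACKGROUND_CLUSTERS = ("C1", "C2")
_BULK_DISPERSION = 0.05


@dataclass
class SimConfig:
    """Parameters of the stated synthetic world (defaults are the world)."""

    n_patients: int = 24
    disease_mix: dict = field(default_factory=lambda: {"glioma": 3 / 7, "BrM": 4 / 7})
    ptrt_high_rate_brm: float = 0.5
    # Beta(a, b) for the true pTRT share of CD8+ cells per patient
    ptrt_frac_low: tuple = (4.0, 76.0)    # mean 0.05
    ptrt_frac_high: tuple = (36.0, 44.0)  # mean 0.45
    n_genes: int = 2000
    n_signature_genes: int = 30
    n_contamination_genes: int = 20
    signature_log2fc: float = 2.0
    contamination_rate: float = 0.1
    clone_zipf_exponent: float = 1.5
    n_cells_per_sample: int = 400
    n_events_per_sample: int = 2000
    n_spatial_cells: int = 800
    n_vessels: int = 8
    pvn_enrichment: float = 3.0
    noise_dispersion: float = 0.5
    n_clones_tumor: int = 120
    n_clones_blood: int = 200
    n_exclusive_clones: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ptrt_high_rate_brm", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.disease_mix.values()) - 1.0) > 1e-9:
            raise ValueError("disease_mix must sum to 1")
        if any(v < 0 for v in self.disease_mix.values()):
            raise ValueError("disease_mix proportions must be non-negative")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("n_genes", "n_signature_genes",
                     "n_contamination_genes", "n_cells_per_sample",
                     "n_events_per_sample", "n_spatial_cells", "n_vessels",
                     "n_clones_tumor", "n_clones_blood"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo = self.ptrt_frac_low[0] / sum(self.ptrt_frac_low)
        hi = self.ptrt_frac_high[0] / sum(self.ptrt_frac_high)
        if hi <= lo:
            raise ValueError("ptrt_frac_high mean must exceed ptrt_frac_low mean")
        if self.noise_dispersion <= 0 or self.pvn_enrichment <= 0:
            raise ValueError("dispersions and odds multipliers must be positive")


@dataclass
class GroundTruth:
    """What was planted, for closed-loop testing downstream."""

    patients: pd.DataFrame  # patient_id, disease, ptrt_label, true_fraction
    signature_genes: list
    contamination_genes: list
    cluster_marker_genes: dict  # background cluster -> genes
    tumor_exclusive_clones: dict  # patient -> junction list
    viral_clones: list
    gate_thresholds: dict  # marker -> [op, threshold on arcsinh scale]
    pvn_enrichment: float
    ptrt_cluster: str = PTRT_CLUSTER


@dataclass
class Cohort:
    sc_counts: pd.DataFrame  # genes x cells
    sc_cells: pd.DataFrame   # cell annotation table
    bulk: ExpressionMatrix
    clonotypes: pd.DataFrame  # AIRR-style
    antigen_db: AntigenDb
    events: pd.DataFrame
    scenes: list
    truth: GroundTruth
    config: SimConfig


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixing; dispersion = 1/shape."""
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=np.maximum(mean, 0) / r)
    return rng.poisson(lam)


def _junctions(rng: np.random.Generator, n: int, existing: set | None = None) -> list[str]:
    """Random CDR3beta-like amino-acid junctions, unique and fresh."""
    existing = set() if existing is None else set(existing)
    out: list[str] = []
    aa = np.array(list(AA_ALPHABET))
    while len(out) < n:
        length = int(rng.integers(6, 11))
        j = "CASS" + "".join(rng.choice(aa, size=length)) + "QYF"
        if j not in existing:
            existing.add(j)
            out.append(j)
    return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full multi-modal cohort with planted ground truth."""
    root = np.random.SeedSequence(config.seed)
    rng_pat, rng_gene, rng_sc, rng_bulk, rng_tcr, rng_flow, rng_sp = (
        np.random.default_rng(s) for s in root.spawn(7)
    )

    # ---- patients and planted labels -------------------------------------
    diseases = list(config.disease_mix)
    probs = np.array([config.disease_mix[d] for d in diseases])
    patients = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        disease = diseases[int(rng_pat.choice(len(diseases), p=probs))]
        if disease == "BrM":
            label = "high" if rng_pat.random() < config.ptrt_high_rate_brm else "low"
        else:
            label = "low"
        a, b = config.ptrt_frac_high if label == "high" else config.ptrt_frac_low
        # bimodal with an empty 15-30% band: no observed sample falls between
        # the low (<15%) and high (>30%) regimes, so the Beta components are
        # truncated outside it
        frac = float(rng_pat.beta(a, b))
        for _ in range(1000):
            if (label == "high" and frac > 0.30) or (label == "low" and frac < 0.15):
                break
            frac = float(rng_pat.beta(a, b))
        patients.append((pid, disease, label, frac))
    truth_pat = pd.DataFrame(
        patients, columns=["patient_id", "disease", "ptrt_label", "true_fraction"]
    ).set_index("patient_id")

    # ---- gene universe ----------------------------------------------------
    genes = pd.Index([f"G{i + 1:04d}" for i in range(config.n_genes)])
    picks = rng_gene.choice(
        config.n_genes,
        size=config.n_signature_genes + config.n_contamination_genes + 20,
        replace=False,
    )
    sig_idx = picks[: config.n_signature_genes]
    contam_idx = picks[config.n_signature_genes:
                       config.n_signature_genes + config.n_contamination_genes]
    mark_idx = picks[config.n_signature_genes + config.n_contamination_genes:]
    signature_genes = list(genes[sig_idx])
    contamination_genes = list(genes[contam_idx])
    cluster_markers = {
        "C1": list(genes[mark_idx[:10]]),
        "C2": list(genes[mark_idx[10:]]),
    }

    base = rng_gene.lognormal(0.0, 1.0, config.n_genes)
    base[contam_idx] = 0.0  # contamination-only genes are silent in T cells
    cluster_means = {}
    for cl in BACKGROUND_CLUSTERS + (PTRT_CLUSTER,):
        m = base.copy()
        if cl == PTRT_CLUSTER:
            m[sig_idx] *= 2.0 ** config.signature_log2fc
        else:
            m[[genes.get_loc(g) for g in cluster_markers[cl]]] *= 4.0
        cluster_means[cl] = m / m.sum()

    cd45neg_means = base * rng_gene.lognormal(0.0, 0.15, config.n_genes)
    cd45neg_means[contam_idx] = rng_gene.lognormal(np.log(50.0), 0.3,
                                                   config.n_contamination_genes)
    cd45neg_means = cd45neg_means / cd45neg_means.sum()
    pop_means = {
        pop: (lambda v: v / v.sum())(base * rng_gene.lognormal(0.0, 0.1, config.n_genes))
        for pop in ("CD4", "MG", "MDM")
    }

    # ---- single-cell counts ----------------------------------------------
    cell_blocks, ann_rows = [], []
    bulk_cd8: dict[str, np.ndarray] = {}
    for pid, row in truth_pat.iterrows():
        f = row["true_fraction"]
        for comp in ("tumor", "blood"):
            n = config.n_cells_per_sample
            if comp == "tumor":
                p_ptrt = f
                bg = (0.7, 0.3) if row["disease"] == "glioma" else (0.5, 0.5)
            else:
                p_ptrt, bg = 0.01, (0.6, 0.4)
            u = rng_sc.random(n)
            clusters = np.where(
                u < p_ptrt, PTRT_CLUSTER,
                np.where(rng_sc.random(n) < bg[0], "C1", "C2"),
            )
            depths = rng_sc.lognormal(np.log(3000.0), 0.25, n)
            mu = np.empty((config.n_genes, n))
            for cl in BACKGROUND_CLUSTERS + (PTRT_CLUSTER,):
                m = clusters == cl
                if m.any():
                    mu[:, m] = np.outer(cluster_means[cl], depths[m])
            counts = _nb_draw(rng_sc, mu, config.noise_dispersion)
            cell_blocks.append(counts.astype(np.int32))
            for k in range(n):
                ann_rows.append((f"{pid}:{comp}:{k:04d}", pid, comp, "CD8",
                                 clusters[k]))
            key = f"{pid}:{comp}"
            bulk_cd8[key] = counts.sum(axis=1)

    sc_counts_arr = (np.concatenate(cell_blocks, axis=1) if cell_blocks
                     else np.empty((config.n_genes, 0), dtype=np.int32))
    sc_cells = pd.DataFrame(
        ann_rows, columns=["cell_id", "patient", "compartment", "lineage", "cluster_id"]
    ).set_index("cell_id")
    sc_counts = pd.DataFrame(sc_counts_arr, index=genes, columns=sc_cells.index)
    sc_cells["n_features"] = (sc_counts_arr > 0).sum(axis=0)
    sc_cells["mito_frac"] = rng_sc.beta(2.0, 30.0, len(sc_cells))

    # ---- bulk sorted populations -----------------------------------------
    bulk_cols, bulk_meta_rows = {}, []
    lib_target = 1_300_000.0

    def disease_label(row) -> str:
        if row["disease"] == "BrM":
            return f"BrM-pTRT-{row['ptrt_label']}"
        return row["disease"]

    for pid, row in truth_pat.iterrows():
        dlab = disease_label(row)
        cd45 = _nb_draw(rng_bulk, cd45neg_means * lib_target, _BULK_DISPERSION)
        for comp in ("tumor", "blood"):
            sid = f"{pid}:{comp}:CD8"
            counts = bulk_cd8[f"{pid}:{comp}"].astype(np.int64)
            if comp == "tumor" and config.contamination_rate > 0:
                counts = counts + rng_bulk.binomial(cd45, config.contamination_rate)
            bulk_cols[sid] = counts
            bulk_meta_rows.append((sid, pid, comp, "CD8", dlab))
            sid4 = f"{pid}:{comp}:CD4"
            bulk_cols[sid4] = _nb_draw(rng_bulk, pop_means["CD4"] * lib_target,
                                       _BULK_DISPERSION)
            bulk_meta_rows.append((sid4, pid, comp, "CD4", dlab))
        sid_n = f"{pid}:tumor:CD45neg"
        bulk_cols[sid_n] = cd45
        bulk_meta_rows.append((sid_n, pid, "tumor", "CD45neg", dlab))
        for pop in ("MG", "MDM"):
            sid_p = f"{pid}:tumor:{pop}"
            bulk_cols[sid_p] = _nb_draw(rng_bulk, pop_means[pop] * lib_target,
                                        _BULK_DISPERSION)
            bulk_meta_rows.append((sid_p, pid, "tumor", pop, dlab))

    bulk = ExpressionMatrix(
        pd.DataFrame(bulk_cols, index=genes),
        pd.DataFrame(
            bulk_meta_rows,
            columns=["sample_id", "patient", "compartment", "population", "disease"],
        ).set_index("sample_id"),
    )

    # ---- TCR repertoires --------------------------------------------------
    viral = _junctions(rng_tcr, 12)
    used = set(viral)
    airr_rows = []
    exclusive: dict[str, list[str]] = {}

    def zipf_sizes(n_clones: int, total: int) -> np.ndarray:
        w = np.arange(1, n_clones + 1, dtype=float) ** (-config.clone_zipf_exponent)
        sizes = np.maximum(np.round(w / w.sum() * total).astype(int), 1)
        return sizes

    for pid, row in truth_pat.iterrows():
        tum_j = _junctions(rng_tcr, config.n_clones_tumor, used)
        used.update(tum_j)
        blood_j = _junctions(rng_tcr, config.n_clones_blood, used)
        used.update(blood_j)
        tum_sizes = zipf_sizes(config.n_clones_tumor, 1200)
        blood_sizes = zipf_sizes(config.n_clones_blood, 1500)
        n_excl = config.n_exclusive_clones
        blood_extra: dict[str, int] = {}
        if row["ptrt_label"] == "high":
            exclusive[pid] = tum_j[:n_excl]
            shared = tum_j[n_excl:n_excl + 30]
            for j in shared:  # small, unexpanded blood presence
                blood_extra[j] = 1
        else:
            exclusive[pid] = []
            for j, s in zip(tum_j[:n_excl], tum_sizes[:n_excl]):
                blood_extra[j] = max(2, int(s * 0.5))  # dually expanded
            n_viral = int(rng_tcr.integers(2, 5))
            vs = list(rng_tcr.choice(viral, size=n_viral, replace=False))
            for j in vs:
                blood_extra[j] = int(rng_tcr.integers(2, 6))
            for j, cnt in zip(vs, rng_tcr.integers(2, 6, size=n_viral)):
                airr_rows.append((pid, "tumor", j, "TRBV20-1", "TRBJ2-1", int(cnt)))
        for j, s in zip(tum_j, tum_sizes):
            airr_rows.append((pid, "tumor", j, "TRBV20-1", "TRBJ2-1", int(s)))
        for j, s in zip(blood_j, blood_sizes):
            airr_rows.append((pid, "blood", j, "TRBV19-1", "TRBJ2-7", int(s)))
        for j, s in blood_extra.items():
            airr_rows.append((pid, "blood", j, "TRBV20-1", "TRBJ2-1", int(s)))

    clonotypes = pd.DataFrame(
        airr_rows,
        columns=["patient_id", "compartment", "junction_aa", "v_call", "j_call",
                 "duplicate_count"],
    )

    db_rows = [(j, sp, int(sc)) for j, sp, sc in zip(
        viral,
        [["CMV", "EBV", "InfluenzaA"][i % 3] for i in range(len(viral))],
        rng_tcr.integers(1, 4, size=len(viral)),
    )]
    decoys = _junctions(rng_tcr, 8, used)  # in DB at score 0, never reportable
    used.update(decoys)
    db_rows += [(j, "CMV", 0) for j in decoys]
    db_rows += [(j, "EBV", int(s)) for j, s in zip(
        _junctions(rng_tcr, 10, used), rng_tcr.integers(1, 4, size=10))]
    antigen_db = AntigenDb(pd.DataFrame(db_rows, columns=["junction_aa", "species", "score"]))

    # ---- flow-cytometry events -------------------------------------------
    # two-component log-normal intensity mixtures; positives ~900, negatives ~20
    pos_mu, neg_mu, sd = np.log(900.0), np.log(20.0), 0.4
    thresh = float(np.arcsinh(np.sqrt(900.0 * 20.0) / 150.0))
    gate_thresholds = {m: [">", thresh] for m in FLOW_MARKERS}
    gate_thresholds["CCR7"] = ["<", thresh]
    #: probability each marker is in its positive component, by cell class
    pos_prob = {
        True: {"CD39": 0.97, "CCR7": 0.03, "PD1": 0.9, "TIM3": 0.8, "CD103": 0.85,
               "CXCL13": 0.8, "Ki67": 0.4, "CD45RO": 0.95},
        False: {"CD39": 0.08, "CCR7": 0.6, "PD1": 0.3, "TIM3": 0.1, "CD103": 0.2,
                "CXCL13": 0.05, "Ki67": 0.05, "CD45RO": 0.7},
    }
    ev_frames = []
    for pid, row in truth_pat.iterrows():
        for comp in ("tumor", "blood"):
            n = config.n_events_per_sample
            p_ptrt = row["true_fraction"] if comp == "tumor" else 0.01
            is_ptrt = rng_flow.random(n) < p_ptrt
            data = {"sample_id": f"{pid}:{comp}", "patient": pid, "compartment": comp}
            frame = pd.DataFrame(data, index=range(n))
            for mk in FLOW_MARKERS:
                p = np.where(is_ptrt, pos_prob[True][mk], pos_prob[False][mk])
                pos = rng_flow.random(n) < p
                mu = np.where(pos, pos_mu, neg_mu)
                frame[mk] = rng_flow.lognormal(mu, sd)
            ev_frames.append(frame)
    events = (pd.concat(ev_frames, ignore_index=True) if ev_frames else
              pd.DataFrame(columns=["sample_id", "patient", "compartment", *FLOW_MARKERS]))

    # ---- spatial scenes ---------------------------------------------------
    scenes = []
    window = (0.0, 0.0, 1000.0, 1000.0)
    for pid, row in truth_pat.iterrows():
        vessels = pd.DataFrame({
            "cx": rng_sp.uniform(60.0, 940.0, config.n_vessels),
            "cy": rng_sp.uniform(60.0, 940.0, config.n_vessels),
            "r": rng_sp.uniform(10.0, 30.0, config.n_vessels),
        })
        cd8_share = 0.12 if row["ptrt_label"] == "high" else 0.05
        n_cells = config.n_spatial_cells
        n_cd8 = int(round(n_cells * cd8_share))
        n_ptrt = int(round(n_cd8 * row["true_fraction"]))
        n_non = n_cd8 - n_ptrt
        rest = n_cells - n_cd8
        n_mg = int(round(rest * 0.18))
        n_mdm = int(round(rest * 0.18))
        n_oi = int(round(rest * 0.12))
        n_ni = rest - n_mg - n_mdm - n_oi
        phenos = (["pTRT"] * n_ptrt + ["nonPTRT_CD8"] * n_non + ["MG"] * n_mg
                  + ["MDM"] * n_mdm + ["other_immune"] * n_oi + ["nonimmune"] * n_ni)
        ptrt_pts = _place_enriched(rng_sp, n_ptrt, vessels, window,
                                   config.pvn_enrichment)
        other_pts = np.column_stack([
            rng_sp.uniform(window[0], window[2], n_cells - n_ptrt),
            rng_sp.uniform(window[1], window[3], n_cells - n_ptrt),
        ])
        pts = np.vstack([ptrt_pts, other_pts])
        cells = pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1],
            "diameter": np.clip(rng_sp.normal(8.5, 1.8, n_cells), 3.0, 15.0),
            "probability": rng_sp.beta(8.0, 2.0, n_cells),
            "phenotype": phenos,
        })
        scenes.append(SpatialScene(cells, vessels, window, scene_id=pid))

    truth = GroundTruth(
        patients=truth_pat,
        signature_genes=signature_genes,
        contamination_genes=contamination_genes,
        cluster_marker_genes=cluster_markers,
        tumor_exclusive_clones=exclusive,
        viral_clones=viral,
        gate_thresholds=gate_thresholds,
        pvn_enrichment=config.pvn_enrichment,
    )
    return Cohort(sc_counts, sc_cells, bulk, clonotypes, antigen_db, events,
                  scenes, truth, config)


def _place_enriched(rng, n, vessels, window, odds) -> np.ndarray:
    """Rejection-sample points with `odds` acceptance weight inside the PVN."""
    from .spatial import pvn_membership

    if n == 0:
        return np.empty((0, 2))
    out = []
    w_max = max(odds, 1.0)
    need = n
    while need > 0:
        batch = max(need * 2, 64)
        cand = np.column_stack([
            rng.uniform(window[0], window[2], batch),
            rng.uniform(window[1], window[3], batch),
        ])
        inside = pvn_membership(cand, vessels)
        w = np.where(inside, odds, 1.0) / w_max
        keep = rng.random(batch) < w
        out.append(cand[keep])
        need = n - sum(len(o) for o in out)
    return np.vstack(out)[:n]


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_cohort(cohort: Cohort, out_dir) -> pd.DataFrame:
    """Write every modality as plain-text files; returns the checksum manifest.

    Formats: Matrix Market + genes/barcodes TSV for single-cell counts, dense
    TSV for bulk counts, AIRR-style TSV for clonotypes, CSV for events and
    spatial tables, JSON for ground truth, YAML for the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    if cohort.truth.patients.empty:
        manifest = pd.DataFrame(columns=["file", "sha256"])
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        return manifest

    scio.mmwrite(out / "sc_counts.mtx",
                 sparse.csc_matrix(cohort.sc_counts.to_numpy()))
    (out / "sc_genes.tsv").write_text("\n".join(cohort.sc_counts.index) + "\n")
    (out / "sc_barcodes.tsv").write_text("\n".join(cohort.sc_counts.columns) + "\n")
    cohort.sc_cells.to_csv(out / "sc_cells.tsv", sep="\t")
    cohort.bulk.counts.to_csv(out / "bulk_counts.tsv", sep="\t")
    cohort.bulk.sample_meta.to_csv(out / "bulk_meta.tsv", sep="\t")
    cohort.clonotypes.to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    cohort.antigen_db.table.to_csv(out / "antigen_db.tsv", sep="\t", index=False)
    cohort.events.to_csv(out / "events.csv", index=False)

    cells = pd.concat(
        [s.cells.assign(scene_id=s.scene_id) for s in cohort.scenes],
        ignore_index=True,
    ) if cohort.scenes else pd.DataFrame(
        columns=["x", "y", "diameter", "probability", "phenotype", "scene_id"])
    vessels = pd.concat(
        [s.vessels.assign(scene_id=s.scene_id) for s in cohort.scenes],
        ignore_index=True,
    ) if cohort.scenes else pd.DataFrame(columns=["cx", "cy", "r", "scene_id"])
    cells.to_csv(out / "spatial_cells.csv", index=False)
    vessels.to_csv(out / "vessels.csv", index=False)
    windows = pd.DataFrame(
        [(s.scene_id, *s.window) for s in cohort.scenes],
        columns=["scene_id", "xmin", "ymin", "xmax", "ymax"],
    )
    windows.to_csv(out / "scene_windows.csv", index=False)

    truth = cohort.truth
    truth_json = {
        "patients": truth.patients.reset_index().to_dict(orient="records"),
        "signature_genes": truth.signature_genes,
        "contamination_genes": truth.contamination_genes,
        "cluster_marker_genes": truth.cluster_marker_genes,
        "tumor_exclusive_clones": truth.tumor_exclusive_clones,
        "viral_clones": truth.viral_clones,
        "gate_thresholds": truth.gate_thresholds,
        "pvn_enrichment": truth.pvn_enrichment,
        "ptrt_cluster": truth.ptrt_cluster,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cohort.config)))

    for f in sorted(p.name for p in out.iterdir()
                    if p.is_file() and p.name != "manifest.tsv"):
        files.append((f, _sha256(out / f)))
    manifest = pd.DataFrame(files, columns=["file", "sha256"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_cohort(in_dir) -> Cohort:
    """Read back a cohort written by :func:`write_cohort` (exact round-trip)."""
    d = Path(in_dir)
    genes = d.joinpath("sc_genes.tsv").read_text().splitlines()
    barcodes = d.joinpath("sc_barcodes.tsv").read_text().splitlines()
    sc_counts = pd.DataFrame(
        np.asarray(scio.mmread(d / "sc_counts.mtx").todense(), dtype=np.int32),
        index=pd.Index(genes), columns=pd.Index(barcodes, name="cell_id"),
    )
    sc_cells = pd.read_csv(d / "sc_cells.tsv", sep="\t", index_col=0)
    bulk = ExpressionMatrix(
        pd.read_csv(d / "bulk_counts.tsv", sep="\t", index_col=0),
        pd.read_csv(d / "bulk_meta.tsv", sep="\t", index_col=0),
    )
    clonotypes = pd.read_csv(d / "clonotypes.tsv", sep="\t")
    antigen_db = AntigenDb(pd.read_csv(d / "antigen_db.tsv", sep="\t"))
    events = pd.read_csv(d / "events.csv")
    cells = pd.read_csv(d / "spatial_cells.csv")
    vessels = pd.read_csv(d / "vessels.csv")
    windows = pd.read_csv(d / "scene_windows.csv")
    scenes = []
    for _, w in windows.iterrows():
        sid = w["scene_id"]
        scenes.append(SpatialScene(
            cells[cells["scene_id"] == sid].drop(columns="scene_id").reset_index(drop=True),
            vessels[vessels["scene_id"] == sid].drop(columns="scene_id").reset_index(drop=True),
            (w["xmin"], w["ymin"], w["xmax"], w["ymax"]),
            scene_id=sid,
        ))
    tj = json.loads(d.joinpath("truth.json").read_text())
    truth = GroundTruth(
        patients=pd.DataFrame(tj["patients"]).set_index("patient_id"),
        signature_genes=tj["signature_genes"],
        contamination_genes=tj["contamination_genes"],
        cluster_marker_genes=tj["cluster_marker_genes"],
        tumor_exclusive_clones=tj["tumor_exclusive_clones"],
        viral_clones=tj["viral_clones"],
        gate_thresholds=tj["gate_thresholds"],
        pvn_enrichment=tj["pvn_enrichment"],
        ptrt_cluster=tj["ptrt_cluster"],
    )
    config = SimConfig(**yaml.safe_load(d.joinpath("config.yaml").read_text()))
    return Cohort(sc_counts, sc_cells, bulk, clonotypes, antigen_db, events,
                  scenes, truth, config)
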