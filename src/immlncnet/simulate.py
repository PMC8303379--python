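"""Synthetic count-matrix generator with planted ground truth.

Emulates a two-genotype (WT / histidine-decarboxylase knockout), optionally
histamine-treated, time-course RNA-seq experiment sampled at 0/1/7 days
after injury, three replicates per arm and timepoint. The generator plants

* differentially expressed genes with a known log2 fold change, persistent
  across timepoints within the affected arm(s);
* latent immunocyte abundance trajectories whose marker genes follow them
  log-additively (so rank-based infiltration scoring can recover them); and
* "immune lncRNAs" whose log-expression tracks one cell type's latent
  abundance at a chosen target Pearson correlation.

Counts are negative-binomial with Var = m + phi * m^2 around the per-gene,
per-sample mean; dispersion below 1e-8 falls back to Poisson. All
randomness flows from a single seeded generator, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, SampleMeta, SignatureSet, ImmLncError

LN2_SQ = math.log(2.0) ** 2

#: 22 immunocyte types; myeloid types (listed first in MYELOID) carry the
#: condition effect by default.
DEFAULT_CELLTYPES = [
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
]

MYELOID = [
    "Neutrophils", "Monocytes", "Macrophages M0", "Macrophages M1",
    "Macrophages M2", "Eosinophils", "Dendritic cells activated",
    "Mast cells activated",
]

ARMS = ("WT_vehicle", "KO_vehicle", "KO_histamine")

COMPARISON_KO = "KO_vs_WT"
COMPARISON_HA = "HA_vs_vehicle"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults encode the emulated design: three arms (wild-type vehicle,
    knockout vehicle, knockout + histamine) x timepoints {0, 1, 7} days x
    3 replicates; NB dispersion 0.1; 10% of genes planted DE at |log2FC| = 2;
    myeloid cell abundances raised one log2 unit in the knockout-vehicle arm
    at days 1 and 7 and restored under histamine; six planted immune
    lncRNAs targeting Pearson r = 0.9 with their cell's latent abundance.
    """

    n_pc_genes: int = 2000
    n_lnc_genes: int = 300
    n_celltypes: int = 22
    markers_per_celltype: int = 10
    replicates: int = 3
    timepoints: tuple[int, ...] = (0, 1, 7)
    arms: tuple[str, ...] = ARMS
    dispersion: float = 0.1
    frac_de: float = 0.1
    de_log2fc: float = 2.0
    abundance_effect: float = 1.0
    marker_gain: float = 3.5
    n_imm_lnc: int = 6
    imm_lnc_r: float = 0.9
    seed: int = 0
    n_affected_celltypes: int = 5
    #: per-(celltype, sample) latent noise, variance 0.1
    celltype_noise_sd: float = math.sqrt(0.1)
    baseline_log2_range: tuple[float, float] = (3.0, 10.0)
    #: planted immune lncRNAs are drawn from the moderately-to-highly
    #: expressed range so the target correlation is attainable given
    #: count-level noise
    imm_lnc_log2_floor: float = 6.0
    library_factor_range: tuple[float, float] = (0.7, 1.3)

    def validate(self) -> None:
        if self.markers_per_celltype * self.n_celltypes > self.n_pc_genes:
            raise ImmLncError(
                "marker demand exceeds protein-coding gene pool: "
                f"{self.markers_per_celltype} x {self.n_celltypes} > {self.n_pc_genes}"
            )
        if self.n_imm_lnc > self.n_lnc_genes:
            raise ImmLncError(
                f"n_imm_lnc ({self.n_imm_lnc}) > n_lnc_genes ({self.n_lnc_genes})"
            )
        if not 0.0 <= self.frac_de <= 1.0:
            raise ImmLncError("frac_de must be in [0, 1]")
        if self.dispersion < 0:
            raise ImmLncError("dispersion must be >= 0")
        if self.n_imm_lnc and not 0.0 < self.imm_lnc_r < 1.0:
            raise ImmLncError("imm_lnc_r must be in (0, 1)")
        if self.n_affected_celltypes > self.n_celltypes:
            raise ImmLncError("n_affected_celltypes > n_celltypes")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ImmLncError(f"unknown arm(s): {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted structure of one simulated experiment.

    ``de_genes`` lists directly planted fold changes (one comparison each).
    ``marker_de`` lists the fold changes induced on affected cell types'
    markers by the abundance shift — these are real expression differences
    a differential test should also find at the affected timepoints.
    """

    de_genes: pd.DataFrame
    celltype_abundance: pd.DataFrame
    marker_assignment: dict[str, str]
    imm_lnc_links: pd.DataFrame
    affected_celltypes: list[str]
    affected_timepoints: list[int]
    marker_de: pd.DataFrame

    def de_set(self, comparison: str) -> set[str]:
        sel = self.de_genes[self.de_genes["comparison"] == comparison]
        return set(sel["gene_id"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes.to_dict(orient="list"),
            "celltype_abundance": {
                "index": list(self.celltype_abundance.index),
                "columns": list(self.celltype_abundance.columns),
                "values": self.celltype_abundance.to_numpy().tolist(),
            },
            "marker_assignment": self.marker_assignment,
            "imm_lnc_links": self.imm_lnc_links.to_dict(orient="list"),
            "affected_celltypes": self.affected_celltypes,
            "affected_timepoints": self.affected_timepoints,
            "marker_de": self.marker_de.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        ab = d["celltype_abundance"]
        return cls(
            de_genes=pd.DataFrame(d["de_genes"]),
            celltype_abundance=pd.DataFrame(
                np.asarray(ab["values"]), index=ab["index"], columns=ab["columns"]
            ),
            marker_assignment=d["marker_assignment"],
            imm_lnc_links=pd.DataFrame(d["imm_lnc_links"]),
            affected_celltypes=d["affected_celltypes"],
            affected_timepoints=d["affected_timepoints"],
            marker_de=pd.DataFrame(d["marker_de"]),
        )


def _sample_meta(cfg: SimulationConfig) -> list[SampleMeta]:
    samples = []
    for arm in cfg.arms:
        genotype, treatment = arm.split("_")
        for tp in cfg.timepoints:
            for rep in range(1, cfg.replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{arm}_d{tp}_r{rep}",
                        genotype=genotype,
                        treatment=treatment,
                        timepoint_days=tp,
                        replicate=rep,
                    )
                )
    return samples


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean m, Var m + phi m^2) draws; Poisson when phi ~ 0."""
    if phi < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SignatureSet, GroundTruth]:
    """Generate (counts, annotation, marker signatures, ground truth).

    Generative model, per gene g and sample s:

    1. baseline log2 mean ``mu_g ~ Uniform(3, 10)``;
    2. latent cell abundance ``a[c, s] = effect * 1[c affected, s in
       knockout-vehicle at day 1 or 7] + eps``, ``eps ~ N(0, 0.1)``
       (variance 0.1);
    3. marker of cell c: log2 mean ``mu_g + b * a[c, s]``;
    4. planted DE gene: log2 mean shifted by the signed effect in the
       affected arm(s), at all timepoints;
    5. planted immune lncRNA linked to cell c: log2 mean ``mu_g +
       b * a[c, s] + N(0, sigma)`` with sigma chosen so the expected
       Pearson r between log2 expression and ``a[c, .]`` — including
       count-level noise — equals ``imm_lnc_r``;
    6. counts ~ NB(mean = library_factor_s * 2^log2mean, dispersion),
       library_factor_s ~ Uniform(0.7, 1.3).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_meta(cfg)
    n_samples = len(samples)
    sample_ids = [s.sample_id for s in samples]

    pc_ids = [f"PC{i:05d}" for i in range(1, cfg.n_pc_genes + 1)]
    lnc_ids = [f"LNC{i:05d}" for i in range(1, cfg.n_lnc_genes + 1)]
    gene_ids = pc_ids + lnc_ids
    n_genes = len(gene_ids)

    if cfg.n_celltypes <= len(DEFAULT_CELLTYPES):
        celltypes = DEFAULT_CELLTYPES[: cfg.n_celltypes]
    else:
        celltypes = DEFAULT_CELLTYPES + [
            f"Immunocyte {i}" for i in range(len(DEFAULT_CELLTYPES) + 1, cfg.n_celltypes + 1)
        ]
    myeloid_present = [c for c in MYELOID if c in celltypes]
    affected = (myeloid_present + [c for c in celltypes if c not in myeloid_present])[
        : cfg.n_affected_celltypes
    ]
    unaffected = [c for c in celltypes if c not in affected]
    affected_tps = [t for t in cfg.timepoints if t != min(cfg.timepoints)]

    lo, hi = cfg.baseline_log2_range
    mu = rng.uniform(lo, hi, size=n_genes)
    log2_mean = np.tile(mu[:, None], (1, n_samples)).astype(float)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # --- latent cell-type abundances -------------------------------------
    ko_raised = np.array(
        [
            s.genotype == "KO"
            and s.treatment == "vehicle"
            and s.timepoint_days in affected_tps
            for s in samples
        ]
    )
    abundance = rng.normal(0.0, cfg.celltype_noise_sd, size=(len(celltypes), n_samples))
    for ci, ct in enumerate(celltypes):
        if ct in affected:
            abundance[ci, ko_raised] += cfg.abundance_effect
    abundance_df = pd.DataFrame(abundance, index=celltypes, columns=sample_ids)

    # --- marker genes -----------------------------------------------------
    marker_assignment: dict[str, str] = {}
    sig_sets: dict[str, list[str]] = {}
    pos = 0
    for ct in celltypes:
        members = pc_ids[pos : pos + cfg.markers_per_celltype]
        pos += cfg.markers_per_celltype
        sig_sets[ct] = members
        for g in members:
            marker_assignment[g] = ct
            log2_mean[gene_index[g]] += cfg.marker_gain * abundance_df.loc[ct].to_numpy()
    signatures = SignatureSet(sig_sets, {ct: "simulated markers" for ct in celltypes})

    marker_rows = []
    if cfg.abundance_effect != 0.0:
        for g, ct in marker_assignment.items():
            if ct not in affected:
                continue
            shift = cfg.marker_gain * cfg.abundance_effect
            if "KO_vehicle" in cfg.arms and "WT_vehicle" in cfg.arms:
                marker_rows.append((g, COMPARISON_KO, shift))
            if "KO_histamine" in cfg.arms and "KO_vehicle" in cfg.arms:
                marker_rows.append((g, COMPARISON_HA, -shift))
    marker_de = pd.DataFrame(marker_rows, columns=["gene_id", "comparison", "log2fc"])

    # --- planted immune lncRNAs ------------------------------------------
    imm_lnc_ids = lnc_ids[: cfg.n_imm_lnc]
    link_rows = []
    link_cts = unaffected if unaffected else celltypes
    for i, lnc in enumerate(imm_lnc_ids):
        ct = link_cts[i % len(link_cts)]
        gi = gene_index[lnc]
        mu[gi] = max(mu[gi], cfg.imm_lnc_log2_floor + (hi - cfg.imm_lnc_log2_floor) * (i / max(cfg.n_imm_lnc, 1)))
        a = abundance_df.loc[ct].to_numpy()
        signal_var = cfg.marker_gain**2 * float(np.var(a))
        # count-level log2 noise via the delta method: Var(log2 Y) ~
        # (1/m + phi) / ln(2)^2 around the typical mean
        m_typical = 2.0 ** mu[gi]
        v_nb = (1.0 / m_typical + cfg.dispersion) / LN2_SQ
        needed = signal_var * (1.0 / cfg.imm_lnc_r**2 - 1.0)
        sigma_extra = math.sqrt(max(needed - v_nb, 0.0))
        log2_mean[gi] = mu[gi] + cfg.marker_gain * a + rng.normal(0.0, sigma_extra, n_samples)
        link_rows.append((lnc, ct, cfg.imm_lnc_r))
    imm_lnc_links = pd.DataFrame(link_rows, columns=["lncRNA", "celltype", "target_r"])

    # --- planted DE genes -------------------------------------------------
    # DE effects are planted in non-marker protein-coding genes only, so the
    # planted DE axis stays orthogonal to the planted lncRNA-immunocyte axis
    # (a DE-shifted lncRNA would genuinely correlate with condition-shifted
    # infiltration scores and blur the link screen's ground truth)
    eligible = [g for g in pc_ids if g not in marker_assignment]
    n_de = int(round(cfg.frac_de * n_genes))
    n_de = min(n_de, len(eligible))
    de_chosen = rng.choice(eligible, size=n_de, replace=False) if n_de else np.array([], dtype=object)
    comparisons_avail = []
    if "KO_vehicle" in cfg.arms and "WT_vehicle" in cfg.arms:
        comparisons_avail.append(COMPARISON_KO)
    if "KO_histamine" in cfg.arms and "KO_vehicle" in cfg.arms:
        comparisons_avail.append(COMPARISON_HA)
    if not comparisons_avail:
        comparisons_avail = [COMPARISON_KO]

    arm_of = np.array([s.arm for s in samples])
    de_rows = []
    for i, g in enumerate(de_chosen):
        comparison = comparisons_avail[i % len(comparisons_avail)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * cfg.de_log2fc
        if comparison == COMPARISON_KO:
            mask = np.isin(arm_of, ["KO_vehicle", "KO_histamine"])
        else:
            mask = arm_of == "KO_histamine"
        log2_mean[gene_index[g], mask] += lfc
        de_rows.append((g, comparison, lfc))
    de_genes = pd.DataFrame(de_rows, columns=["gene_id", "comparison", "log2fc"])

    # --- counts -----------------------------------------------------------
    lf_lo, lf_hi = cfg.library_factor_range
    library_factor = rng.uniform(lf_lo, lf_hi, size=n_samples)
    mean = library_factor[None, :] * np.exp2(log2_mean)
    counts = _nb_counts(rng, mean, cfg.dispersion)
    mat = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), samples
    )

    # --- annotation -------------------------------------------------------
    chroms = [str(i) for i in range(1, 20)] + ["X", "Y"]
    ann = pd.DataFrame(
        {
            "biotype": ["protein_coding"] * len(pc_ids) + ["lncRNA"] * len(lnc_ids),
            "chromosome": [chroms[i % len(chroms)] for i in range(n_genes)],
            "start": [1000 * (i // len(chroms) + 1) for i in range(n_genes)],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    truth = GroundTruth(
        de_genes=de_genes,
        celltype_abundance=abundance_df,
        marker_assignment=marker_assignment,
        imm_lnc_links=imm_lnc_links,
        affected_celltypes=list(affected),
        affected_timepoints=affected_tps,
        marker_de=marker_de,
    )
    return mat, ann, signatures, truth


def simulate_null(cfg: SimulationConfig) -> ExpressionMatrix:
    """Null experiment: no DE, no abundance shifts, no planted lncRNAs."""
    null_cfg = replace(cfg, frac_de=0.0, abundance_effect=0.0, n_imm_lnc=0)
    mat, _, _, truth = simulate_experiment(null_cfg)
    assert truth.de_genes.empty and truth.imm_lnc_links.empty and truth.marker_de.empty
    return mat


def write_simulated_inputs(
    outdir: str | Path,
    mat: ExpressionMatrix,
    annotation: pd.DataFrame,
    signatures: SignatureSet,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the generator's outputs in the same formats the readers accept."""
    from . import data as _data

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
        "signatures": outdir / "signatures.gmt",
        "truth": outdir / "truth.json",
    }
    _data.write_counts(mat, paths["counts"], paths["metadata"])
    _data.write_annotation(annotation, paths["annotation"])
    _data.write_gmt(signatures, paths["signatures"])
    truth.to_json(paths["truth"])
    return paths
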