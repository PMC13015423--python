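"""Synthetic cohorts with known ground truth for every pipeline stage.

The cohort data this pipeline was designed for are controlled-access, so each
analysis stage ships with a generator emulating the statistical structure it
assumes:

* **Variant catalogs** — per-tumor somatic deletion lists whose size spectrum
  is a two-regime mixture: with the class-specific MMEJ weight a deletion is
  drawn from the MMEJ-characteristic 6-20 bp regime (discrete uniform), else
  from the 1-5 bp regime. HRD tumors carry a high weight, HR-proficient tumors
  a low one. Neoantigen burden is Poisson-coupled to the count of scar-derived
  frameshift deletions (MMEJ regime, length not divisible by 3), so HRD tumors
  gain neoantigens through the repair scar rather than through total mutation
  count; TMB uses a fixed 30 Mb exome denominator.
* **Spatial samples** — planar point patterns of macrophages and CD8 T cells
  on a rectangular window with a tunable CD8-to-APC attraction (null:
  attraction 0, uniform CD8 placement) and optional proximity-dependent
  expression reinforcement.
* **Immune census** — per-tumor cell-type compositions interpolating from
  macrophage-dominant to T/NK-rich along an increasing neoantigen gradient,
  with program-gene expression by cell type.
* **Survival** — exponential event times per group with independent
  exponential censoring.

All generators are pure functions of their configuration including the seed:
the same seed yields byte-identical tables. Expression is generated directly
on the log1p scale (downstream analyses only threshold at 0 and rank); no
sequence context is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

EXOME_MB = 30.0  # assumed exome footprint for TMB, in Mb
MMEJ_RANGE = (6, 20)  # bp, inclusive
SHORT_RANGE = (1, 5)  # bp, inclusive

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Variant_Classification",
]

CELL_TYPES = ("Macrophage", "CD8T", "CD4T", "B", "NKT", "Treg")

# macrophage-dominant and immune-diverse composition endpoints for the census
_COMP_MAC_DOMINANT = np.array([0.70, 0.08, 0.08, 0.05, 0.05, 0.04])
_COMP_DIVERSE = np.array([0.10, 0.25, 0.25, 0.15, 0.15, 0.10])

#: program genes carried by the census, with per-cell-type mean log1p expression
CENSUS_GENES: dict[str, dict[str, float]] = {
    "HLA-DRA": {"Macrophage": 1.5, "B": 1.2},
    "CD74": {"Macrophage": 1.4, "B": 1.1},
    "GZMB": {"CD8T": 1.3, "NKT": 1.2},
    "PRF1": {"CD8T": 1.2, "NKT": 1.1},
    "NKG7": {"CD8T": 1.1, "NKT": 1.3},
    "STAT1": {"CD8T": 0.8, "CD4T": 0.7, "Macrophage": 0.6},
    "IRF1": {"CD8T": 0.7, "CD4T": 0.6, "Macrophage": 0.5},
    "FOXP3": {"Treg": 1.4},
}
_CENSUS_BASE = 0.2  # background mean for unlisted (gene, type) pairs
_CENSUS_SD = 0.3


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_rate(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative rate, got {value}")


@dataclass(frozen=True)
class GenomicSimConfig:
    """Study conditions for the variant-catalog generator.

    ``mmej_weight_*`` is the probability that a deletion in that tumor class is
    drawn from the 6-20 bp MMEJ regime; ``coupling_alpha`` is the expected
    neoantigens contributed per scar-derived (MMEJ-regime) frameshift deletion
    on top of ``neoantigen_baseline``, reflecting that the repair scar — not
    total mutation count — is the frameshift-neoantigen source;
    ``neoantigen_noise`` > 0 switches the neoantigen draw from Poisson to a
    gamma-Poisson mixture with that dispersion (variance mu + noise * mu^2).
    """

    n_tumors: int = 60
    hrd_fraction: float = 0.5
    lambda_del: float = 40.0
    mmej_weight_hrd: float = 0.6
    mmej_weight_hrp: float = 0.05
    coupling_alpha: float = 0.5
    neoantigen_baseline: float = 5.0
    lambda_missense: float = 60.0
    neoantigen_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        _check_proportion("hrd_fraction", self.hrd_fraction)
        _check_proportion("mmej_weight_hrd", self.mmej_weight_hrd)
        _check_proportion("mmej_weight_hrp", self.mmej_weight_hrp)
        for name in ("lambda_del", "coupling_alpha", "neoantigen_baseline",
                     "lambda_missense", "neoantigen_noise"):
            _check_rate(name, getattr(self, name))


@dataclass(frozen=True)
class SpatialSimConfig:
    """Study conditions for one simulated spatial sample.

    ``attraction`` is the probability that a CD8 cell is placed as a Gaussian
    displacement (scale ``sigma`` um) from a random APC-like macrophage rather
    than uniformly; ``expr_effect`` is an additive log1p increment applied to
    both antigen-presentation genes of macrophages within 20 um of a CD8 cell
    after placement. ``coexpr_zero`` controls how often non-APC macrophages
    have both genes at 0 rather than just one.
    """

    window: tuple[float, float] = (500.0, 500.0)
    n_macrophages: int = 300
    apc_fraction: float = 0.3
    n_cd8: int = 150
    attraction: float = 0.0
    sigma: float = 5.0
    expr_effect: float = 0.0
    coexpr_zero: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValueError("window area must be > 0")
        if self.n_macrophages < 0 or self.n_cd8 < 0:
            raise ValueError("counts must be >= 0")
        _check_proportion("apc_fraction", self.apc_fraction)
        _check_proportion("attraction", self.attraction)
        _check_proportion("coexpr_zero", self.coexpr_zero)
        _check_rate("sigma", self.sigma)
        _check_rate("expr_effect", self.expr_effect)


def simulate_variant_catalogs(
    config: GenomicSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-tumor somatic variant tables and the latent truth table.

    Returns ``(variants, truth)``. ``variants`` is one MAF-like table over all
    tumors (deletions as ``Variant_Type=DEL`` with ``Tumor_Seq_Allele2='-'``,
    missense as SNPs). ``truth`` records, per tumor: class, per-bin deletion
    counts, frameshift count, neoantigen burden and TMB.
    """
    rng = np.random.default_rng(config.seed)
    variant_rows: list[tuple] = []
    truth_rows: list[dict] = []

    for i in range(config.n_tumors):
        tumor = f"T{i + 1:03d}"
        is_hrd = rng.random() < config.hrd_fraction
        weight = config.mmej_weight_hrd if is_hrd else config.mmej_weight_hrp

        n_del = rng.poisson(config.lambda_del)
        from_mmej = rng.random(n_del) < weight
        lengths = np.where(
            from_mmej,
            rng.integers(MMEJ_RANGE[0], MMEJ_RANGE[1] + 1, size=n_del),
            rng.integers(SHORT_RANGE[0], SHORT_RANGE[1] + 1, size=n_del),
        )
        frameshift = lengths % 3 != 0
        fs_count = int(frameshift.sum())
        mmej_fs_count = int((frameshift & from_mmej).sum())

        mu = config.coupling_alpha * mmej_fs_count + config.neoantigen_baseline
        if config.neoantigen_noise > 0 and mu > 0:
            shape = 1.0 / config.neoantigen_noise
            mu = rng.gamma(shape, mu / shape)
        neoantigens = int(rng.poisson(mu))

        n_missense = int(rng.poisson(config.lambda_missense))
        tmb = (n_missense + n_del) / EXOME_MB

        chroms = rng.integers(1, 23, size=n_del + n_missense).astype(str)
        positions = rng.integers(1, 100_000_000, size=n_del + n_missense)
        for j in range(n_del):
            variant_rows.append(
                (
                    tumor, chroms[j], int(positions[j]),
                    "A" * int(lengths[j]), "-", "DEL",
                    "Frame_Shift_Del" if frameshift[j] else "In_Frame_Del",
                )
            )
        for j in range(n_del, n_del + n_missense):
            variant_rows.append(
                (tumor, chroms[j], int(positions[j]), "A", "T", "SNP",
                 "Missense_Mutation")
            )

        truth_rows.append(
            dict(
                tumor_id=tumor,
                subgroup="HRD" if is_hrd else "HRP",
                n_deletions=int(n_del),
                b1_5=int(((lengths >= 1) & (lengths <= 5)).sum()),
                b6_13=int(((lengths >= 6) & (lengths <= 13)).sum()),
                b14_20=int(((lengths >= 14) & (lengths <= 20)).sum()),
                b21_50=0,
                frameshift_count=fs_count,
                mmej_frameshift_count=mmej_fs_count,
                n_missense=n_missense,
                neoantigen_burden=neoantigens,
                tmb=tmb,
            )
        )

    variants = pd.DataFrame(variant_rows, columns=MAF_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return variants, truth


def simulate_spatial_sample(config: SpatialSimConfig) -> pd.DataFrame:
    """Draw one spatial cell table (macrophages with ground-truth APC flag,
    CD8 T cells, log1p HLA-DRA/CD74 values).

    Macrophages are uniform on the window; ``apc_fraction`` of them are
    APC-like with both genes strictly positive, the rest have at least one
    gene at 0. Each CD8 cell is either attracted (Gaussian displacement from a
    random APC-like macrophage, clipped to the window) or uniform. After
    placement, macrophages within 20 um of any CD8 cell gain ``expr_effect``
    on both genes. ``attraction > 0`` with zero APC-like macrophages is
    rejected.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.window
    n_mac = config.n_macrophages
    n_apc = int(round(config.apc_fraction * n_mac))
    if config.attraction > 0 and n_apc == 0:
        raise ValueError("attraction > 0 requires at least one APC-like macrophage")

    mac_xy = rng.uniform([0, 0], [w, h], size=(n_mac, 2))
    apc_flag = np.zeros(n_mac, dtype=bool)
    if n_apc:
        apc_flag[rng.choice(n_mac, size=n_apc, replace=False)] = True

    dra = rng.uniform(0.2, 2.0, size=n_mac)
    cd74 = rng.uniform(0.2, 2.0, size=n_mac)
    for idx in np.flatnonzero(~apc_flag):
        u = rng.random()
        if u < config.coexpr_zero:
            dra[idx] = cd74[idx] = 0.0
        elif u < config.coexpr_zero + (1 - config.coexpr_zero) / 2:
            dra[idx] = 0.0
        else:
            cd74[idx] = 0.0

    attracted = rng.random(config.n_cd8) < config.attraction
    cd8_xy = rng.uniform([0, 0], [w, h], size=(config.n_cd8, 2))
    n_att = int(attracted.sum())
    if n_att:
        anchors = mac_xy[np.flatnonzero(apc_flag)[rng.integers(0, n_apc, size=n_att)]]
        displaced = anchors + rng.normal(0.0, config.sigma, size=(n_att, 2))
        cd8_xy[attracted] = np.clip(displaced, [0, 0], [w, h])

    if config.expr_effect > 0 and config.n_cd8 and n_mac:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(cd8_xy).query(mac_xy, k=1)
        near = d <= 20.0
        dra[near] += config.expr_effect
        cd74[near] += config.expr_effect

    mac = pd.DataFrame(
        {
            "cell_id": [f"MAC{i}" for i in range(n_mac)],
            "sample_id": "S1",
            "x_um": mac_xy[:, 0],
            "y_um": mac_xy[:, 1],
            "cell_type": "Macrophage",
            "HLA-DRA": dra,
            "CD74": cd74,
            "apc_truth": apc_flag,
        }
    )
    cd8 = pd.DataFrame(
        {
            "cell_id": [f"CD8_{i}" for i in range(config.n_cd8)],
            "sample_id": "S1",
            "x_um": cd8_xy[:, 0],
            "y_um": cd8_xy[:, 1],
            "cell_type": "CD8T",
            "HLA-DRA": 0.0,
            "CD74": 0.0,
            "apc_truth": False,
        }
    )
    return pd.concat([mac, cd8], ignore_index=True)


def simulate_immune_census(
    n_tumors: int,
    cells_per_tumor: int,
    gradient_strength: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an immune census whose composition shifts along a neoantigen
    gradient.

    Tumors get increasing neoantigen burdens; with ``gradient_strength`` g the
    cell-type composition of the i-th tumor is the mixture
    ``(1 - g*t) * macrophage_dominant + g*t * diverse`` with t the burden rank
    scaled to [0, 1], so g=0 gives identical compositions and g=1 the full
    70% -> 10% macrophage sweep. Per-tumor shifted MDF increases with burden
    plus noise. Returns ``(cells, tumors)``.
    """
    if n_tumors < 2:
        raise ValueError("n_tumors must be >= 2")
    if cells_per_tumor < 1:
        raise ValueError("cells_per_tumor must be >= 1")
    if not 0.0 <= gradient_strength <= 1.0:
        raise ValueError("gradient_strength must be in [0, 1]")

    rng = np.random.default_rng(seed)
    burdens = np.round(np.linspace(5, 150, n_tumors)).astype(int)
    t_scaled = np.linspace(0.0, 1.0, n_tumors)
    mdf = np.maximum(0.0, 0.04 * burdens + rng.normal(0.0, 0.5, size=n_tumors))

    genes = list(CENSUS_GENES)
    cell_rows = []
    for i in range(n_tumors):
        tumor = f"T{i + 1:03d}"
        comp = (1 - gradient_strength * t_scaled[i]) * _COMP_MAC_DOMINANT + (
            gradient_strength * t_scaled[i]
        ) * _COMP_DIVERSE
        comp = comp / comp.sum()
        types = rng.choice(len(CELL_TYPES), size=cells_per_tumor, p=comp)
        for j, t_idx in enumerate(types):
            ctype = CELL_TYPES[t_idx]
            row = {
                "cell_id": f"{tumor}_C{j}",
                "tumor_id": tumor,
                "cell_type": ctype,
            }
            for g in genes:
                mean = CENSUS_GENES[g].get(ctype, _CENSUS_BASE)
                row[g] = max(0.0, rng.normal(mean, _CENSUS_SD))
            cell_rows.append(row)

    cells = pd.DataFrame(cell_rows)
    tumors = pd.DataFrame(
        {
            "tumor_id": [f"T{i + 1:03d}" for i in range(n_tumors)],
            "neoantigen_burden": burdens,
            "shifted_mdf": mdf,
        }
    )
    return cells, tumors


def simulate_survival(
    n_per_group: int,
    median_by_group: Mapping[str, float],
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw exponential survival times per group with independent exponential
    censoring.

    Event times are exponential with rate ln2/median; censoring times are
    exponential with rate ``censor_rate`` (0 means no censoring). The event
    indicator is 1 when the event precedes censoring.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    _check_rate("censor_rate", censor_rate)
    for g, m in median_by_group.items():
        if not (np.isfinite(m) and m > 0):
            raise ValueError(f"median for group {g!r} must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    for g, m in median_by_group.items():
        lam = np.log(2) / m
        t_event = rng.exponential(1.0 / lam, size=n_per_group)
        if censor_rate > 0:
            t_cens = rng.exponential(1.0 / censor_rate, size=n_per_group)
        else:
            t_cens = np.full(n_per_group, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for k in range(n_per_group):
            rows.append(
                dict(
                    subject_id=f"{g}_{k}",
                    time=float(time[k]),
                    event=int(event[k]),
                    group=g,
                )
            )
    return pd.DataFrame(rows)
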