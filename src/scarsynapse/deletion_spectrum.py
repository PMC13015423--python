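"""MMEJ Deletion Footprint (MDF) scoring from somatic deletion calls.

Microhomology-mediated end joining (MMEJ) is an error-prone, POLQ-dependent
double-strand-break repair pathway that leaves short deletions (characteristically
6-20 bp) at microhomology sites. The MDF summarises this scar per tumor: somatic
deletions are binned by net length (1-5, 6-13, 14-20, 21-50 bp), the raw MDF is
the summed count in the 6-13 and 14-20 bp bins, and raw counts are z-scored
across the cohort (sample standard deviation) and shifted so the cohort minimum
maps to zero. Quartiles are assigned from the standardized values.

The footprint is purely size-based: no sequence context (microhomology) is
inspected, and deletions longer than 50 bp are tracked for QC but excluded from
all bins and from the MDF itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed size bins, in bp. Lengths above the last edge go to ``overflow_gt50``.
BIN_EDGES: tuple[tuple[int, int], ...] = ((1, 5), (6, 13), (14, 20), (21, 50))
BIN_COLUMNS: tuple[str, ...] = ("b1_5", "b6_13", "b14_20", "b21_50")
#: Bins whose counts sum to the raw MDF (the MMEJ-characteristic 6-20 bp range).
MDF_BINS: tuple[str, ...] = ("b6_13", "b14_20")

SPECTRUM_COLUMNS = ["tumor_id", *BIN_COLUMNS, "overflow_gt50"]


@dataclass(frozen=True)
class DeletionRecord:
    """One somatic deletion, with its net length in bp.

    ``deletion_length`` is the difference of reference and alternate allele
    lengths and must be >= 1. ``frameshift`` is True/False when known from the
    annotation, otherwise None (callers may fall back to ``length % 3 != 0``).
    """

    tumor_id: str
    chrom: str
    pos: int
    ref_len: int
    alt_len: int
    frameshift: bool | None = None

    def __post_init__(self) -> None:
        if self.ref_len - self.alt_len < 1:
            raise ValueError(
                f"not a deletion: ref_len={self.ref_len}, alt_len={self.alt_len}"
            )

    @property
    def deletion_length(self) -> int:
        return self.ref_len - self.alt_len


def parse_deletions(
    variant_file: str | Path,
    dialect: str,
    tumor_id: str | None = None,
) -> list[DeletionRecord]:
    """Extract deletion records from a VCF or MAF file.

    Deletion length is the reference-minus-alternate allele length; insertions
    and length-preserving substitutions are excluded. Multi-allelic VCF records
    are split per alternate allele before the length comparison. Complex
    substitutions where both alleles differ but the reference is longer count
    as deletions of the net length difference.

    Parameters
    ----------
    variant_file
        Path to a VCF 4.x file (optionally bgzipped) or a MAF TSV.
    dialect
        ``"vcf"`` or ``"maf"``.
    tumor_id
        Tumor identifier to stamp on VCF records (defaults to the first sample
        name in the VCF header, else the file stem). Ignored for MAF, which
        carries ``Tumor_Sample_Barcode`` per row.

    Returns
    -------
    list of :class:`DeletionRecord`

    Raises
    ------
    ValueError
        Unknown dialect, or a file that does not parse as the named standard.
        Individually malformed records are skipped with a logged warning.
    """
    path = Path(variant_file)
    if dialect == "vcf":
        return _parse_vcf(path, tumor_id)
    if dialect == "maf":
        return _parse_maf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'vcf' or 'maf'")


def _parse_vcf(path: Path, tumor_id: str | None) -> list[DeletionRecord]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # file-level failure is a hard error
        raise ValueError(f"cannot parse {path} as VCF: {exc}") from exc

    if tumor_id is None:
        tumor_id = vcf.samples[0] if vcf.samples else path.stem

    records: list[DeletionRecord] = []
    n_skipped = 0
    for variant in vcf:
        ref = variant.REF
        for alt in variant.ALT:  # multi-allelic records split per allele
            if alt is None or not alt.isalpha():
                n_skipped += 1
                continue
            if len(ref) > len(alt):
                records.append(
                    DeletionRecord(
                        tumor_id=tumor_id,
                        chrom=str(variant.CHROM),
                        pos=int(variant.POS),
                        ref_len=len(ref),
                        alt_len=len(alt),
                    )
                )
    if n_skipped:
        logger.warning("%s: skipped %d malformed ALT allele(s)", path, n_skipped)
    return records


_MAF_REQUIRED = {"Tumor_Sample_Barcode", "Reference_Allele", "Tumor_Seq_Allele2"}


def _parse_maf(path: Path) -> list[DeletionRecord]:
    try:
        maf = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise ValueError(f"cannot parse {path} as MAF TSV: {exc}") from exc
    missing = _MAF_REQUIRED - set(maf.columns)
    if missing:
        raise ValueError(f"{path}: MAF is missing required columns {sorted(missing)}")

    has_class = "Variant_Classification" in maf.columns
    records: list[DeletionRecord] = []
    n_skipped = 0
    for row in maf.itertuples(index=False):
        ref = str(getattr(row, "Reference_Allele"))
        alt = str(getattr(row, "Tumor_Seq_Allele2"))
        if alt in ("-", "", "nan"):
            alt_len = 0  # MAF deletion convention: '-' means no residual bases
        elif alt.isalpha():
            alt_len = len(alt)
        else:
            n_skipped += 1
            continue
        if not ref.isalpha():
            n_skipped += 1
            continue
        ref_len = len(ref)
        if ref_len <= alt_len:
            continue  # insertion or substitution, not a deletion

        frameshift: bool | None = None
        if has_class:
            vc = str(getattr(row, "Variant_Classification"))
            if vc == "Frame_Shift_Del":
                frameshift = True
            elif vc == "In_Frame_Del":
                frameshift = False
        if frameshift is None:
            frameshift = (ref_len - alt_len) % 3 != 0

        pos = getattr(row, "Start_Position", 0)
        records.append(
            DeletionRecord(
                tumor_id=str(getattr(row, "Tumor_Sample_Barcode")),
                chrom=str(getattr(row, "Chromosome", "")),
                pos=int(pos) if str(pos).isdigit() else 0,
                ref_len=ref_len,
                alt_len=alt_len,
                frameshift=frameshift,
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    return records


def bin_spectrum(
    records: list[DeletionRecord] | pd.DataFrame,
    tumor_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Count deletions per tumor in the closed size bins 1-5, 6-13, 14-20, 21-50 bp.

    Lengths above 50 bp are counted in ``overflow_gt50`` (QC only). Tumors named
    in ``tumor_ids`` but absent from ``records`` get an all-zero spectrum, so a
    cohort manifest can enforce that zero-deletion tumors stay in the cohort.
    """
    if isinstance(records, pd.DataFrame):
        lengths = records["deletion_length"].to_numpy()
        tumors = records["tumor_id"].to_numpy()
    else:
        lengths = np.array([r.deletion_length for r in records], dtype=int)
        tumors = np.array([r.tumor_id for r in records], dtype=object)

    all_ids = list(dict.fromkeys(tumors))  # first-seen order
    if tumor_ids is not None:
        for t in tumor_ids:
            if t not in all_ids:
                all_ids.append(t)

    counts = {t: dict.fromkeys([*BIN_COLUMNS, "overflow_gt50"], 0) for t in all_ids}
    for t, length in zip(tumors, lengths):
        for col, (lo, hi) in zip(BIN_COLUMNS, BIN_EDGES):
            if lo <= length <= hi:
                counts[t][col] += 1
                break
        else:
            counts[t]["overflow_gt50"] += 1

    out = pd.DataFrame(
        [{"tumor_id": t, **counts[t]} for t in all_ids], columns=SPECTRUM_COLUMNS
    )
    return out


def compute_mdf(spectra: pd.DataFrame, sd_mode: str = "sample") -> pd.DataFrame:
    """Score the MMEJ Deletion Footprint across a cohort.

    ``raw_mdf`` is the per-tumor count of 6-20 bp deletions (6-13 plus 14-20 bp
    bins). ``z_mdf`` standardizes the raw counts with the cohort mean and sample
    (n-1) standard deviation; ``shifted_mdf`` subtracts the cohort minimum z so
    the smallest value is exactly 0 (an affine, display-oriented shift).
    Quartiles come from linear-interpolation empirical quantiles of ``z_mdf`` at
    0.25/0.5/0.75; values <= Q1 get quartile 1, and so on, so ties go to the
    lower quartile. ``mdf_high`` flags tumors strictly above the cohort median.

    A zero-variance cohort yields z = 0 everywhere with a warning (quartiles
    degenerate to 1); a single-tumor cohort is an error because nothing can be
    standardized.
    """
    if sd_mode != "sample":
        raise ValueError(f"unsupported sd_mode {sd_mode!r}")
    if len(spectra) < 2:
        raise ValueError("cohort standardization needs at least 2 tumors")

    out = spectra.copy()
    raw = out[list(MDF_BINS)].sum(axis=1).to_numpy(dtype=float)
    out["raw_mdf"] = raw.astype(int)

    sd = raw.std(ddof=1)
    if sd > 0:
        z = (raw - raw.mean()) / sd
    else:
        warnings.warn(
            "cohort MDF standard deviation is 0; all z-scores set to 0",
            stacklevel=2,
        )
        z = np.zeros_like(raw)
    out["z_mdf"] = z
    out["shifted_mdf"] = z - z.min()

    q1, q2, q3 = np.quantile(z, [0.25, 0.5, 0.75])
    quartile = np.full(len(z), 4, dtype=int)
    quartile[z <= q3] = 3
    quartile[z <= q2] = 2
    quartile[z <= q1] = 1
    out["quartile"] = quartile
    out["mdf_high"] = z > np.median(z)
    return out
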