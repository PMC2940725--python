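"""Genotype matrix I/O, SNP filtering, and run manifests.

The primary interchange format is a tab- (or whitespace-) delimited text
matrix of allele counts, individuals in rows and SNPs in columns, with an
optional header row of SNP identifiers and an optional leading column of
individual identifiers.  Entries are the number of copies of the reference
allele (0, 1 or 2); a plink ``.raw``-style dosage table (header starting
``FID IID ...``) is also accepted.  All writers in the package emit files
their readers round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("popfactor")

MISSING_SENTINELS = {"NA", "na", "NaN", "nan", ".", "-9"}

PLINK_RAW_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed into a valid matrix."""


@dataclass
class GenotypeMatrix:
    """An n individuals x p SNPs matrix of allele counts.

    ``values`` holds counts of the reference allele per individual and SNP.
    Integer-coded data must lie in {0, 1, 2}; real values are permitted
    after preprocessing (e.g. mean imputation).  Fitting requires a
    complete matrix: missing entries are rejected at construction.
    """

    values: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GenotypeFormatError("genotype values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise GenotypeFormatError("genotype matrix contains non-finite entries")
        n, p = self.values.shape
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(n)]
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(p)]
        if len(self.individual_ids) != n or len(self.snp_ids) != p:
            raise GenotypeFormatError("id lengths do not match matrix shape")
        ints = np.rint(self.values)
        if np.allclose(self.values, ints):
            bad = (ints < 0) | (ints > 2)
            if np.any(bad):
                i, j = np.argwhere(bad)[0]
                raise GenotypeFormatError(
                    f"integer-coded entry out of range {{0,1,2}} at "
                    f"individual {self.individual_ids[i]!r}, SNP {self.snp_ids[j]!r}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP reference allele frequency, sum(x) / 2n."""
        return self.values.mean(axis=0) / 2.0


def _looks_numeric(token: str) -> bool:
    if token in MISSING_SENTINELS:
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_genotypes(
    path: str | Path,
    transpose: bool = False,
    missing_policy: str = "error",
) -> GenotypeMatrix:
    """Read a delimited genotype matrix.

    Header row and leading id column are auto-detected (a writer from this
    package always emits both).  ``missing_policy`` is ``"error"`` (the
    model does not handle missing data) or ``"column_mean_impute"``, which
    replaces a missing entry with the mean count of its SNP.  ``transpose``
    reads SNP-major files (SNPs in rows).
    """
    if missing_policy not in ("error", "column_mean_impute"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeFormatError(f"{path}: empty file")

    first = lines[0].split()
    if first[:2] == ["FID", "IID"]:
        return _read_plink_raw(path, lines, missing_policy)

    has_header = not all(_looks_numeric(tok) for tok in first)
    header = lines[0].split() if has_header else None
    data_lines = lines[1:] if has_header else lines

    rows: list[list[str]] = []
    row_ids: list[str] = []
    has_row_ids = bool(data_lines) and not _looks_numeric(data_lines[0].split()[0])
    width = None
    for lineno, ln in enumerate(data_lines, start=2 if has_header else 1):
        toks = ln.split()
        if has_row_ids:
            row_ids.append(toks[0])
            toks = toks[1:]
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise GenotypeFormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(toks)} fields, expected {width})"
            )
        rows.append(toks)

    col_ids: list[str] = []
    if header is not None:
        # header may or may not carry a label for the id column
        col_ids = header[1:] if has_row_ids and len(header) == width + 1 else header
        if len(col_ids) != width:
            raise GenotypeFormatError(
                f"{path}: header has {len(col_ids)} SNP ids for {width} columns"
            )

    values = _parse_cells(rows, row_ids, col_ids, missing_policy, path)
    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return GenotypeMatrix(values, list(row_ids), list(col_ids))


def _read_plink_raw(path: Path, lines: list[str], missing_policy: str) -> GenotypeMatrix:
    header = lines[0].split()
    meta = [c for c in header if c in PLINK_RAW_META_COLS]
    snp_ids = header[len(meta):]
    rows, row_ids = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split()
        if len(toks) != len(header):
            raise GenotypeFormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(toks)} fields, expected {len(header)})"
            )
        row_ids.append(toks[1] if len(meta) >= 2 else toks[0])
        rows.append(toks[len(meta):])
    values = _parse_cells(rows, row_ids, snp_ids, missing_policy, path)
    return GenotypeMatrix(values, row_ids, snp_ids)


def _parse_cells(
    rows: list[list[str]],
    row_ids: list[str],
    col_ids: list[str],
    missing_policy: str,
    path: Path,
) -> np.ndarray:
    n = len(rows)
    p = len(rows[0]) if rows else 0
    values = np.empty((n, p), dtype=float)
    missing_mask = np.zeros((n, p), dtype=bool)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            if tok in MISSING_SENTINELS:
                if missing_policy == "error":
                    iid = row_ids[i] if row_ids else f"row {i}"
                    sid = col_ids[j] if col_ids else f"column {j}"
                    raise GenotypeFormatError(
                        f"{path}: missing genotype at individual {iid!r}, SNP {sid!r} "
                        f"(policy=error; the model requires a complete matrix)"
                    )
                missing_mask[i, j] = True
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError:
                    raise GenotypeFormatError(
                        f"{path}: unparseable entry {tok!r} at row {i}, column {j}"
                    ) from None
    if missing_mask.any():
        col_means = np.nanmean(values, axis=0)
        if np.any(np.isnan(col_means)):
            raise GenotypeFormatError(f"{path}: a SNP column is entirely missing")
        ii, jj = np.where(missing_mask)
        values[ii, jj] = col_means[jj]
        log.info("imputed %d missing genotypes with column means", missing_mask.sum())
    return values


def write_genotypes(X: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as TSV with SNP header and id column."""
    df = pd.DataFrame(X.values, index=X.individual_ids, columns=X.snp_ids)
    ints = np.rint(X.values)
    if np.allclose(X.values, ints):
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="id")


def filter_maf(X: GenotypeMatrix, min_maf: float) -> tuple[GenotypeMatrix, list[str]]:
    """Remove SNPs with minor allele frequency below ``min_maf``.

    Returns the filtered matrix and the removed SNP ids.  Frequency is the
    sample reference-allele frequency sum(x)/2n; the minor allele frequency
    is min(f, 1-f).
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    freq = X.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= min_maf
    if not keep.any():
        raise GenotypeFormatError("all SNPs removed by the MAF filter")
    removed = [sid for sid, k in zip(X.snp_ids, keep) if not k]
    if removed:
        log.info("MAF filter removed %d of %d SNPs", len(removed), X.p)
    return (
        GenotypeMatrix(
            X.values[:, keep],
            list(X.individual_ids),
            [sid for sid, k in zip(X.snp_ids, keep) if k],
        ),
        removed,
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic sites from a VCF into ALT-allele counts (0/1/2).

    Multiallelic sites and sites with missing genotypes are skipped with a
    warning.  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, snp_ids = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        if np.any(gt == 2):
            skipped += 1
            continue
        counts = np.where(gt == 3, 2, gt)
        rows.append(counts)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if skipped:
        log.warning("skipped %d multiallelic or incomplete VCF sites", skipped)
    if not rows:
        raise GenotypeFormatError(f"{path}: no usable biallelic sites")
    return GenotypeMatrix(np.array(rows, dtype=float).T, sample_ids, snp_ids)


def write_matrix_tsv(
    M: np.ndarray,
    path: str | Path,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
    index_label: str = "id",
) -> None:
    M = np.atleast_2d(np.asarray(M))
    if row_ids is None:
        row_ids = [f"row{i}" for i in range(M.shape[0])]
    if col_ids is None:
        col_ids = [f"col{j}" for j in range(M.shape[1])]
    pd.DataFrame(M, index=row_ids, columns=col_ids).to_csv(
        path, sep="\t", index_label=index_label
    )


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    input_paths: list[str | Path] | None = None,
    final_logliks: list[float] | None = None,
) -> Path:
    """Write the run manifest recording command, config, seed and inputs.

    Every CLI output directory contains exactly one ``manifest.json``;
    reruns with identical manifest inputs reproduce deterministic outputs
    bit-exactly.
    """
    from popfactor import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "seed": seed,
        "version": __version__,
        "input_digests": {
            str(p): file_digest(p) for p in (input_paths or []) if Path(p).exists()
        },
    }
    if final_logliks is not None:
        manifest["final_logliks"] = final_logliks
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
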