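"""Genotype datasets, missing-genotype imputation and SNP block maps.

Genotypes are additively coded: 0, 1 or 2 copies of the minor allele.
Missing calls are stored as :data:`MISSING` (-1) in an ``int8`` matrix of
shape ``(n_individuals, n_snps)``.  The phenotype is binary
(0 = control, 1 = case).

Two text formats are supported: PLINK additive ``.raw`` files (the output
of ``plink --recode A``) and a plain delimited matrix with an individual
id column, a 0/1 phenotype column and one 0/1/2/NA column per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file contains an invalid cell."""


@dataclass
class GenotypeDataset:
    """Case/control genotype matrix with additive 0/1/2 coding.

    Parameters
    ----------
    genotypes
        ``(n, p)`` int8 matrix over {0, 1, 2, MISSING}.
    phenotype
        Length-``n`` vector over {0 (control), 1 (case)}.
    snp_ids
        Length-``p`` unique SNP identifiers.
    snp_positions
        Optional ``(chromosome, basepair)`` per SNP, 1-based basepairs.
    individual_ids
        Optional length-``n`` individual identifiers.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: Sequence[str]
    snp_positions: Optional[Sequence[tuple]] = None
    individual_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.uint8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.phenotype.shape != (self.genotypes.shape[0],):
            raise ValueError("phenotype length must match number of individuals")
        valid = (self.genotypes == MISSING) | (
            (self.genotypes >= 0) & (self.genotypes <= 2)
        )
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype value {self.genotypes[bad[0], bad[1]]} "
                f"at individual {bad[0]}, SNP {bad[1]}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")
        ids = list(self.snp_ids)
        if len(ids) != self.genotypes.shape[1]:
            raise ValueError("snp_ids length must match number of SNPs")
        if len(set(ids)) != len(ids):
            raise ValueError("snp_ids must be unique")
        self.snp_ids = ids

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_missing(self) -> int:
        return int((self.genotypes == MISSING).sum())

    def has_both_classes(self) -> bool:
        return len(np.unique(self.phenotype)) == 2

    def subset(self, rows: np.ndarray) -> "GenotypeDataset":
        """Row subset (individuals), preserving SNP metadata."""
        rows = np.asarray(rows)
        return replace(
            self,
            genotypes=self.genotypes[rows],
            phenotype=self.phenotype[rows],
            individual_ids=(
                [self.individual_ids[i] for i in rows]
                if self.individual_ids is not None
                else None
            ),
        )


@dataclass(frozen=True)
class BlockMap:
    """Partition of SNP indices into ordered groups (blocks).

    ``blocks`` is a tuple of int arrays; their concatenation is a
    permutation of ``0..p-1``.  ``block_size_B`` records the nominal block
    size used to build a contiguous map (the last block may be shorter).
    """

    blocks: tuple
    block_size_B: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "blocks",
            tuple(np.asarray(b, dtype=np.int64) for b in self.blocks),
        )
        flat = np.concatenate(self.blocks) if self.blocks else np.empty(0, int)
        if len(np.unique(flat)) != flat.size:
            raise ValueError("blocks must be disjoint")
        if flat.size and not np.array_equal(np.sort(flat), np.arange(flat.size)):
            raise ValueError("blocks must cover exactly 0..p-1")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_snps(self) -> int:
        return int(sum(len(b) for b in self.blocks))

    def sizes(self) -> list[int]:
        return [len(b) for b in self.blocks]

    def block_of_snp(self) -> np.ndarray:
        """Length-p vector mapping SNP index -> block index."""
        out = np.empty(self.n_snps, dtype=np.int64)
        for g, b in enumerate(self.blocks):
            out[b] = g
        return out


def make_block_map(n_snps: int, B: int) -> BlockMap:
    """Partition ``0..n_snps-1`` into contiguous blocks of ``B`` SNPs.

    The final block keeps the remainder (size between 1 and ``B``).
    """
    if B <= 0:
        raise ValueError(f"block size B must be positive, got {B}")
    if B > n_snps:
        raise ValueError(f"B={B} exceeds number of SNPs ({n_snps})")
    edges = np.arange(0, n_snps + B, B)
    edges[-1] = min(edges[-1], n_snps)
    blocks = tuple(
        np.arange(lo, hi) for lo, hi in zip(edges[:-1], edges[1:]) if hi > lo
    )
    return BlockMap(blocks=blocks, block_size_B=B)


def shuffle_block_map(block_map: BlockMap, seed: int) -> BlockMap:
    """Destroy SNP adjacency while keeping the block-size multiset.

    All SNP indices are globally permuted (seeded) and regrouped into
    blocks of the original sizes.  Used to test whether a method exploits
    the local correlation structure rather than mere dimension reduction.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(block_map.n_snps)
    blocks = []
    pos = 0
    for size in block_map.sizes():
        blocks.append(np.sort(perm[pos : pos + size]))
        pos += size
    return BlockMap(blocks=tuple(blocks), block_size_B=block_map.block_size_B)


def impute_missing(data: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Randomly fill missing genotypes from each SNP's observed distribution.

    Each missing entry at SNP ``j`` is drawn i.i.d. from the empirical
    distribution of the non-missing genotypes of SNP ``j``, pooled over the
    joint cohort of cases and controls.  Non-missing entries are unchanged
    and the fill is deterministic given ``seed``.
    """
    G = data.genotypes
    if not (G == MISSING).any():
        return data
    rng = np.random.default_rng(seed)
    out = G.copy()
    miss_rows, miss_cols = np.nonzero(G == MISSING)
    # Per-SNP genotype frequencies of the observed calls.
    for j in np.unique(miss_cols):
        col = G[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(
                f"SNP {data.snp_ids[j]!r} (index {j}) has no observed genotypes"
            )
        counts = np.bincount(obs, minlength=3).astype(float)
        probs = counts / counts.sum()
        rows = miss_rows[miss_cols == j]
        out[rows, j] = rng.choice(3, size=rows.size, p=probs).astype(np.int8)
    return replace(data, genotypes=out)


def read_genotypes(path, format: str = "plink_raw") -> GenotypeDataset:
    """Read a genotype dataset from text.

    ``plink_raw``: whitespace-delimited, header ``FID IID PAT MAT SEX
    PHENOTYPE SNP1 ...``; genotype cells in {0,1,2,NA}; phenotype coded
    1=control, 2=case (rows with other phenotypes are dropped with a
    logged count).

    ``delimited_matrix``: comma- or tab-separated with a header; first
    column individual id, second column phenotype in {0,1}, remaining
    columns 0/1/2/NA.
    """
    path = Path(path)
    data = _read_genotypes_inner(path, format)
    if not data.has_both_classes():
        # prediction-only datasets are legitimate; fitting will refuse
        logger.warning("%s: phenotype has a single class", path)
    return data


def _read_genotypes_inner(path: Path, format: str) -> GenotypeDataset:
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing_meta = [c for c in _PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise GenotypeParseError(
                f"{path}: missing PLINK .raw columns {missing_meta}"
            )
        snp_cols = [c for c in df.columns if c not in _PLINK_META_COLS]
        pheno_raw = pd.to_numeric(df["PHENOTYPE"], errors="coerce")
        keep = pheno_raw.isin([1, 2]).to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d individuals with missing phenotype", n_dropped)
        df = df.loc[keep]
        phenotype = (pheno_raw[keep] == 2).to_numpy().astype(np.uint8)
        geno = _parse_genotype_cells(df[snp_cols], path, header_offset=1)
        ids = list(df["IID"].astype(str))
        # PLINK suffixes SNP names with the counted allele (rs123_A).
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        if len(set(snp_ids)) != len(snp_ids):
            snp_ids = snp_cols
        return GenotypeDataset(geno, phenotype, snp_ids, individual_ids=ids)
    if format == "delimited_matrix":
        sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.shape[1] < 3:
            raise GenotypeParseError(f"{path}: need id, phenotype and SNP columns")
        id_col, pheno_col = df.columns[0], df.columns[1]
        pheno_raw = pd.to_numeric(df[pheno_col], errors="coerce")
        if not pheno_raw.isin([0, 1]).all():
            bad = int(np.nonzero(~pheno_raw.isin([0, 1]).to_numpy())[0][0])
            raise GenotypeParseError(
                f"{path}: row {bad + 2}: phenotype must be 0 or 1"
            )
        phenotype = pheno_raw.to_numpy().astype(np.uint8)
        geno = _parse_genotype_cells(df[df.columns[2:]], path, header_offset=1)
        return GenotypeDataset(
            geno,
            phenotype,
            list(df.columns[2:]),
            individual_ids=list(df[id_col].astype(str)),
        )
    raise ValueError(f"unknown format {format!r}")


def _parse_genotype_cells(df: pd.DataFrame, path, header_offset: int) -> np.ndarray:
    cells = df.to_numpy(dtype=object)
    out = np.empty(cells.shape, dtype=np.int8)
    str_cells = df.astype(str).to_numpy()
    is_na = np.isin(str_cells, ("NA", "nan", "None", ""))
    out[is_na] = MISSING
    ok = is_na.copy()
    for code in ("0", "1", "2"):
        hit = str_cells == code
        out[hit] = int(code)
        ok |= hit
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise GenotypeParseError(
            f"{path}: row {r + 1 + header_offset}, column {df.columns[c]!r}: "
            f"invalid genotype {cells[r, c]!r} (expected 0, 1, 2 or NA)"
        )
    return out


def write_plink_raw(data: GenotypeDataset, path) -> None:
    """Write a dataset as a PLINK additive ``.raw`` text file."""
    path = Path(path)
    ids = data.individual_ids or [f"ind{i}" for i in range(data.n_individuals)]
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(data.snp_ids) + "\n")
        for i in range(data.n_individuals):
            row = data.genotypes[i]
            cells = " ".join("NA" if g == MISSING else str(int(g)) for g in row)
            fh.write(f"{ids[i]} {ids[i]} 0 0 0 {int(data.phenotype[i]) + 1} {cells}\n")


def write_block_map(block_map: BlockMap, snp_ids: Sequence[str], path) -> None:
    """Serialize a block map as two-column TSV (snp_id, block_index)."""
    block_of = block_map.block_of_snp()
    with open(path, "w") as fh:
        fh.write("snp_id\tblock\n")
        for j, sid in enumerate(snp_ids):
            fh.write(f"{sid}\t{block_of[j]}\n")


def read_block_map(path, snp_ids: Sequence[str]) -> BlockMap:
    """Read a two-column TSV block map, validating against ``snp_ids``."""
    df = pd.read_csv(path, sep="\t")
    order = {sid: i for i, sid in enumerate(snp_ids)}
    unknown = set(df["snp_id"].astype(str)) - set(order)
    if unknown:
        raise ValueError(f"block map references unknown SNPs: {sorted(unknown)[:5]}")
    groups: dict[int, list[int]] = {}
    for sid, blk in zip(df["snp_id"].astype(str), df["block"].astype(int)):
        groups.setdefault(blk, []).append(order[sid])
    blocks = tuple(np.sort(groups[k]) for k in sorted(groups))
    sizes = [len(b) for b in blocks]
    return BlockMap(blocks=blocks, block_size_B=max(sizes))
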