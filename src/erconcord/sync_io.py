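"""Reading, writing and polarizing PoPoolation2 ``sync`` allele-count data.

The sync format is tab-separated: chromosome, 1-based position, reference
base, then one ``A:T:C:G:N:*`` count column per population sample.  A
*column map* — an ordered list of ``(replicate, timepoint)`` pairs, one per
population column — links columns to the experimental design; it is always
supplied explicitly, never inferred from the file.

Internally counts live in a :class:`CountTensor`: integer read counts of a
tracked ("rising") allele and of the other allele, indexed by
(SNP, replicate, timepoint).  ``N`` and ``*`` (deletion) counts never enter
the depth; sites are reduced to their two most frequent alleles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BASES = ("A", "T", "C", "G")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


class SyncParseError(ValueError):
    """Raised on a malformed sync line; message names the offending line."""


@dataclass
class CountTensor:
    """Biallelic read counts for S SNPs x R replicates x T timepoints.

    Attributes
    ----------
    chrom, pos : arrays of length S (1-based positions).
    rising, depth : int arrays of shape (S, R, T); ``rising`` counts the
        tracked allele, ``depth`` the total of the two retained alleles.
    alleles : (S, 2) array of base letters, column 0 = tracked allele.
    timepoints : generation labels, strictly increasing from 0.
    replicates : replicate labels (1..R by default).
    multiallelic : bool mask, True where a third allele exceeded the
        configured minor-count floor (site kept biallelic by top-2 rule).
    """

    chrom: np.ndarray
    pos: np.ndarray
    rising: np.ndarray
    depth: np.ndarray
    alleles: np.ndarray
    timepoints: np.ndarray
    replicates: np.ndarray
    multiallelic: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.rising = np.asarray(self.rising, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.timepoints = np.asarray(self.timepoints, dtype=np.int64)
        self.replicates = np.asarray(self.replicates)
        if self.rising.shape != self.depth.shape:
            raise ValueError("rising and depth shapes differ")
        if (self.rising < 0).any() or (self.rising > self.depth).any():
            raise ValueError("counts must satisfy 0 <= rising <= depth")
        tp = self.timepoints
        if len(tp) and (tp[0] != 0 or (np.diff(tp) <= 0).any()):
            raise ValueError("timepoints must be strictly increasing from 0")
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_snps, dtype=bool)

    @property
    def n_snps(self) -> int:
        return self.rising.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.rising.shape[1] if self.rising.ndim == 3 else 0

    @property
    def n_timepoints(self) -> int:
        return self.rising.shape[2] if self.rising.ndim == 3 else 0

    def frequencies(self) -> np.ndarray:
        """Rising-allele frequencies, NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depth > 0, self.rising / self.depth, np.nan)

    def snp_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.chrom, self.pos], names=["chrom", "pos"]
        )

    def snp_ids(self) -> np.ndarray:
        """``chrom:pos`` string identifiers (stable SNP keys)."""
        return np.array(
            [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
        )

    def subset(self, mask_or_idx) -> "CountTensor":
        i = np.asarray(mask_or_idx)
        return CountTensor(
            chrom=self.chrom[i],
            pos=self.pos[i],
            rising=self.rising[i],
            depth=self.depth[i],
            alleles=self.alleles[i],
            timepoints=self.timepoints,
            replicates=self.replicates,
            multiallelic=self.multiallelic[i],
            provenance=dict(self.provenance),
        )


def read_sync(
    path,
    column_map: Sequence[tuple[int, int]],
    minor_count_floor: int = 2,
) -> CountTensor:
    """Read a PoPoolation2 sync file into a :class:`CountTensor`.

    Parameters
    ----------
    column_map : ordered ``(replicate, timepoint)`` pair per population
        column; replicate labels are arbitrary hashables, timepoints are
        generation numbers.
    minor_count_floor : a site whose third-most-frequent base exceeds this
        total count is flagged ``multiallelic`` (still kept, top-2 rule).

    The two retained alleles are the two most frequent bases summed over
    all population columns; the more frequent overall becomes the initially
    tracked allele (use :func:`polarize_rising` for the rising convention).
    """
    path = Path(path)
    reps = sorted({r for r, _ in column_map})
    tps = sorted({t for _, t in column_map})
    rep_pos = {r: i for i, r in enumerate(reps)}
    tp_pos = {t: i for i, t in enumerate(tps)}
    ncols = len(column_map)

    chroms: list[str] = []
    poss: list[int] = []
    counts_rows: list[np.ndarray] = []  # each (ncols, 4)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 + ncols:
                raise SyncParseError(
                    f"{path}:{lineno}: expected {3 + ncols} fields, "
                    f"got {len(parts)}"
                )
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            row = np.empty((ncols, 4), dtype=np.int64)
            for j, cell in enumerate(parts[3:]):
                try:
                    a, t, c, g, *_ = cell.split(":")
                    row[j] = (int(a), int(t), int(c), int(g))
                except ValueError as exc:
                    raise SyncParseError(
                        f"{path}:{lineno}: bad count column {j + 1!r}: {cell}"
                    ) from exc
            counts_rows.append(row)

    S = len(chroms)
    R, T = len(reps), len(tps)
    if S == 0:
        empty = np.zeros((0, R, T), dtype=np.int64)
        return CountTensor(
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            rising=empty,
            depth=empty.copy(),
            alleles=np.zeros((0, 2), dtype=object),
            timepoints=np.array(tps, dtype=np.int64),
            replicates=np.array(reps),
            provenance={"path": str(path), "column_map": list(column_map)},
        )

    counts = np.stack(counts_rows)  # (S, ncols, 4)
    totals = counts.sum(axis=1)  # (S, 4) per-base totals over all columns
    order = np.argsort(-totals, axis=1, kind="stable")
    top2 = order[:, :2]
    third = totals[np.arange(S), order[:, 2]]
    multi = third > minor_count_floor

    maj = counts[np.arange(S)[:, None], :, top2[:, :1]].squeeze(1)  # (S,ncols)
    mino = counts[np.arange(S)[:, None], :, top2[:, 1:2]].squeeze(1)

    rising = np.zeros((S, R, T), dtype=np.int64)
    depth = np.zeros((S, R, T), dtype=np.int64)
    for j, (r, t) in enumerate(column_map):
        ri, ti = rep_pos[r], tp_pos[t]
        rising[:, ri, ti] = maj[:, j]
        depth[:, ri, ti] = maj[:, j] + mino[:, j]

    base_arr = np.array(BASES, dtype=object)
    alleles = base_arr[top2]
    return CountTensor(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        rising=rising,
        depth=depth,
        alleles=alleles,
        timepoints=np.array(tps, dtype=np.int64),
        replicates=np.array(reps),
        multiallelic=multi,
        provenance={"path": str(path), "column_map": list(column_map)},
    )


def write_sync(ct: CountTensor, path, ref_base: str | None = None) -> None:
    """Write a CountTensor as a sync file (inverse of :func:`read_sync`).

    Columns follow the tensor's provenance column map if present, else
    replicate-major order (r1t0, r1t1, ..., r2t0, ...). The reference-base
    column is the tracked allele unless ``ref_base`` overrides it.
    """
    cmap = ct.provenance.get("column_map")
    if cmap is None:
        cmap = [(r, t) for r in ct.replicates for t in ct.timepoints]
    rep_pos = {r: i for i, r in enumerate(ct.replicates)}
    tp_pos = {t: i for i, t in enumerate(ct.timepoints)}

    with open(path, "w") as fh:
        for s in range(ct.n_snps):
            a0, a1 = ct.alleles[s]
            cells = []
            for r, t in cmap:
                ri, ti = rep_pos[r], tp_pos[t]
                c = [0, 0, 0, 0, 0, 0]
                c[_BASE_IDX[a0]] = int(ct.rising[s, ri, ti])
                c[_BASE_IDX[a1]] = int(
                    ct.depth[s, ri, ti] - ct.rising[s, ri, ti]
                )
                cells.append(":".join(map(str, c)))
            ref = ref_base if ref_base is not None else a0
            fh.write(
                f"{ct.chrom[s]}\t{ct.pos[s]}\t{ref}\t" + "\t".join(cells) + "\n"
            )


def polarize_rising(ct: CountTensor) -> CountTensor:
    """Relabel each SNP so the tracked allele is the rising one.

    The rising allele is the one whose frequency change from generation 0
    to the last sampled generation, averaged over replicates (cells with
    zero depth ignored), is >= 0.  Exact ties track the allele that is
    minor at generation 0 (averaged over replicates).  Idempotent; depth
    is preserved at every cell.
    """
    if ct.n_timepoints < 2:
        raise ValueError("polarization needs at least two timepoints")
    f = ct.frequencies()
    d_af = np.nanmean(f[:, :, -1] - f[:, :, 0], axis=1)
    f0 = np.nanmean(f[:, :, 0], axis=1)
    flip = (d_af < 0) | ((d_af == 0) & (f0 > 0.5))
    rising = np.where(flip[:, None, None], ct.depth - ct.rising, ct.rising)
    alleles = ct.alleles.copy()
    alleles[flip] = alleles[flip][:, ::-1]
    return CountTensor(
        chrom=ct.chrom,
        pos=ct.pos,
        rising=rising,
        depth=ct.depth,
        alleles=alleles,
        timepoints=ct.timepoints,
        replicates=ct.replicates,
        multiallelic=ct.multiallelic,
        provenance={**ct.provenance, "polarized": "rising"},
    )


def segregating_mask(ct: CountTensor) -> np.ndarray:
    """Boolean mask: SNP segregating in every replicate and generation.

    False whenever any replicate x timepoint cell has zero depth or a
    frequency of exactly 0 or 1.
    """
    f = ct.frequencies()
    ok = (ct.depth > 0) & (f > 0) & (f < 1)
    return ok.all(axis=(1, 2))


# ---------------------------------------------------------------------------
# Block assignments

def read_block_table(path) -> pd.DataFrame:
    """Read a block-assignment TSV with columns chrom, pos, block_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "block_id": str})
    missing = {"chrom", "pos", "block_id"} - set(df.columns)
    if missing:
        raise ValueError(f"block table missing columns: {sorted(missing)}")
    return df


def write_block_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def block_members(
    blocks: pd.DataFrame, ct: CountTensor
) -> dict[str, np.ndarray]:
    """Map block_id -> indices into ``ct`` of member SNPs, in SNP order.

    Raises if a member SNP is absent from the tensor.
    """
    idx = pd.Series(np.arange(ct.n_snps), index=ct.snp_index())
    key = pd.MultiIndex.from_arrays(
        [blocks["chrom"].to_numpy(), blocks["pos"].to_numpy()]
    )
    try:
        positions = idx.loc[key].to_numpy()
    except KeyError as exc:
        raise ValueError(f"block member SNP not in dataset: {exc}") from exc
    out: dict[str, np.ndarray] = {}
    for bid, grp in pd.DataFrame(
        {"i": positions, "block_id": blocks["block_id"].to_numpy()}
    ).groupby("block_id", sort=True):
        out[str(bid)] = np.sort(grp["i"].to_numpy())
    return out


def write_provenance(path, payload: dict) -> None:
    """Write a JSON sidecar recording inputs, seeds and parameters."""
    with open(str(path) + ".provenance.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str, sort_keys=True)
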