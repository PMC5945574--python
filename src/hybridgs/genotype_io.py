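"""Genotype I/O, SNP quality control, marker-set intersection and numeric encoding.

Genotypes live in a :class:`GenotypeMatrix`: samples x biallelic markers with
calls coded -1/0/+1 (NaN = missing before imputation).  The coding convention
after :func:`impute_and_encode` is the one used throughout genomic selection
here: -1 = homozygote of the minor allele, 0 = heterozygote, +1 = homozygote
of the major allele.  At the I/O layer, +1 always corresponds to the
ref/ref genotype of the file, so re-orienting a marker to minor/major also
swaps its stored ref and alt alleles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

MARKER_COLUMNS = ["id", "chromosome", "position", "ref_allele", "alt_allele"]


class GenotypeParseError(ValueError):
    """A record could not be parsed in the declared dialect."""


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one biallelic SNP (1-based position)."""

    id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.id}")


@dataclass
class QCThresholds:
    """Per-group maximum missing rate; 'above' is strict (> removes)."""

    max_missing_by_group: dict[str, float]

    def __post_init__(self):
        for g, f in self.max_missing_by_group.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"threshold for group {g!r} outside [0,1]: {f}")


@dataclass
class GenotypeMatrix:
    """Samples x markers call matrix with marker metadata.

    ``calls`` is float (samples x markers); values are -1/0/+1 (or expected
    dosages +-0.5 for hybrids of residually heterozygous parents), NaN before
    imputation.  ``markers`` is a DataFrame with columns id, chromosome,
    position, ref_allele, alt_allele.
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["id"].tolist()

    def is_encoded(self) -> bool:
        """True if no missing calls remain."""
        return not np.isnan(self.calls).any()

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in ids]
        groups = {s: self.groups[s] for s in ids if self.groups and s in self.groups} or None
        return GenotypeMatrix(list(ids), self.markers.copy(), self.calls[rows], groups)

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.samples),
            self.markers.iloc[idx].reset_index(drop=True),
            self.calls[:, idx],
            dict(self.groups) if self.groups else None,
        )


def _markers_frame(infos: list[MarkerInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.id, m.chromosome, m.position, m.ref_allele, m.alt_allele) for m in infos],
        columns=MARKER_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

_GT_TO_CODE = {(0, 0): 1.0, (0, 1): 0.0, (1, 0): 0.0, (1, 1): -1.0}


def read_genotype_table(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype panel from VCF or the TSV dialect.

    VCF: biallelic SNP records only (others skipped with a logged count);
    genotypes taken from GT, ``./.`` becomes missing; ref/ref -> +1,
    het -> 0, alt/alt -> -1.
    TSV: first column sample id, header row of marker ids, values in
    {-1, 0, 1, NA} (real-valued dosages accepted); marker metadata from the
    sidecar ``<path>.markers.tsv``.
    """
    if format == "vcf":
        return _read_vcf(str(path))
    if format == "tsv":
        return _read_tsv(str(path))
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    infos: list[MarkerInfo] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        infos.append(MarkerInfo(mid, rec.CHROM, rec.POS, rec.REF, alts[0]))
        col = np.full(len(samples), MISSING)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[i] = _GT_TO_CODE[(min(a, 1), min(b, 1))]
        columns.append(col)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    if not infos:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    calls = np.column_stack(columns)
    return GenotypeMatrix(samples, _markers_frame(infos), calls)


def _marker_sidecar(path: str) -> str:
    return str(path) + ".markers.tsv"


def _read_tsv(path: str) -> GenotypeMatrix:
    try:
        table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise GenotypeParseError(f"cannot parse TSV {path}: {exc}") from exc
    samples = table.index.astype(str).tolist()
    calls = table.replace("NA", np.nan).to_numpy(dtype=float) if table.shape[1] else np.empty((len(samples), 0))
    meta = pd.read_csv(_marker_sidecar(path), sep="\t", dtype={"position": int})
    meta.columns = MARKER_COLUMNS
    if list(meta["id"]) != list(table.columns):
        raise GenotypeParseError(f"marker ids in {path} disagree with sidecar metadata")
    return GenotypeMatrix(samples, meta, calls)


def write_genotype_table(g: GenotypeMatrix, path, format: str = "tsv") -> None:
    """Write ``g`` so that :func:`read_genotype_table` round-trips exactly."""
    if format == "vcf":
        _write_vcf(g, str(path))
    elif format == "tsv":
        _write_tsv(g, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


_CODE_TO_GT = {1.0: "0/0", 0.0: "0/1", -1.0: "1/1"}


def _write_vcf(g: GenotypeMatrix, path: str) -> None:
    non_integer = ~np.isin(g.calls[~np.isnan(g.calls)], [-1.0, 0.0, 1.0])
    if non_integer.any():
        raise ValueError("VCF cannot represent fractional dosages; write TSV instead")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j, m in g.markers.iterrows():
            gts = [
                "./." if np.isnan(c) else _CODE_TO_GT[c] for c in g.calls[:, j]
            ]
            fh.write(
                f"{m['chromosome']}\t{m['position']}\t{m['id']}\t"
                f"{m['ref_allele']}\t{m['alt_allele']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _format_code(c: float) -> str:
    if np.isnan(c):
        return "NA"
    if c == int(c):
        return str(int(c))
    return repr(c)


def _write_tsv(g: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id"] + g.marker_ids) + "\n")
        for i, s in enumerate(g.samples):
            fh.write("\t".join([s] + [_format_code(c) for c in g.calls[i]]) + "\n")
    g.markers.to_csv(_marker_sidecar(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC / encoding / intersection
# ---------------------------------------------------------------------------


def qc_filter_missing(g: GenotypeMatrix, thresholds: QCThresholds) -> GenotypeMatrix:
    """Drop markers whose missing rate exceeds a group's threshold.

    A marker is retained iff for every group listed in ``thresholds`` its
    missing fraction within that group is <= the group's threshold.  Groups
    not listed impose no constraint; the sample set and marker order are
    preserved.
    """
    if g.groups is None:
        raise ValueError("qc_filter_missing requires sample group labels")
    keep = np.ones(g.n_markers, dtype=bool)
    for group, thr in thresholds.max_missing_by_group.items():
        rows = [i for i, s in enumerate(g.samples) if g.groups.get(s) == group]
        if not rows:
            continue
        frac = np.isnan(g.calls[rows]).mean(axis=0)
        keep &= frac <= thr
    if not keep.any():
        logger.warning("QC removed every marker")
    return g.subset_markers(np.flatnonzero(keep))


def impute_and_encode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Impute missing calls and orient codes to minor/major alleles.

    Missing calls are replaced by the per-marker mode of the observed codes
    (ties -> 0).  The minor allele is then determined from the allele
    frequency over all samples; markers are re-oriented so that +1 is the
    major-allele homozygote (ties at frequency 0.5 broken by lexicographic
    allele order: the lexicographically smaller allele is treated as major).
    Re-orienting swaps the stored ref/alt alleles so that +1 always maps to
    ref/ref on write.  Markers missing in every sample are dropped.
    """
    calls = g.calls.copy()
    all_missing = np.isnan(calls).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} markers with no observed calls",
            stacklevel=2,
        )
        g = g.subset_markers(np.flatnonzero(~all_missing))
        calls = g.calls.copy()

    # mode imputation over codes {-1, 0, +1}; ties -> 0
    for j in range(calls.shape[1]):
        col = calls[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        obs = col[~nan]
        counts = {c: int((obs == c).sum()) for c in (-1.0, 0.0, 1.0)}
        best = max(counts.values())
        modes = [c for c, n in counts.items() if n == best]
        col[nan] = modes[0] if len(modes) == 1 else 0.0

    markers = g.markers.copy().reset_index(drop=True)
    # frequency of the allele currently coded +1 (the file's ref allele)
    freq_plus = (calls + 1.0).mean(axis=0) / 2.0
    for j in range(calls.shape[1]):
        f = freq_plus[j]
        ref, alt = markers.at[j, "ref_allele"], markers.at[j, "alt_allele"]
        flip = f < 0.5 or (f == 0.5 and alt < ref)
        if flip:
            calls[:, j] = -calls[:, j]
            markers.at[j, "ref_allele"], markers.at[j, "alt_allele"] = alt, ref
    return GenotypeMatrix(list(g.samples), markers, calls, dict(g.groups) if g.groups else None)


def intersect_marker_sets(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two panels to markers shared by (chromosome, position, alleles).

    Alleles must match as written or as a ref/alt swap; swapped markers in
    ``b`` are re-encoded to ``a``'s orientation by negating their codes
    (no strand flipping; A/T and C/G swaps are treated like any other swap,
    with a warning).  Output marker order follows ``a``.
    """
    b_index: dict[tuple, int] = {}
    for j, m in b.markers.iterrows():
        b_index[(m["chromosome"], int(m["position"]))] = j

    a_keep: list[int] = []
    b_keep: list[int] = []
    b_negate: list[bool] = []
    n_ambiguous = 0
    for j, m in a.markers.iterrows():
        key = (m["chromosome"], int(m["position"]))
        jb = b_index.get(key)
        if jb is None:
            continue
        mb = b.markers.iloc[jb]
        pair_a = (m["ref_allele"], m["alt_allele"])
        pair_b = (mb["ref_allele"], mb["alt_allele"])
        if pair_a == pair_b:
            neg = False
        elif pair_a == pair_b[::-1]:
            neg = True
            if set(pair_a) in ({"A", "T"}, {"C", "G"}):
                n_ambiguous += 1
        else:
            continue
        a_keep.append(j)
        b_keep.append(jb)
        b_negate.append(neg)
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} strand-ambiguous (A/T or C/G) swapped markers re-encoded "
            "by negation; verify strands upstream if this is unexpected",
            stacklevel=2,
        )
    a_out = a.subset_markers(np.array(a_keep, dtype=int))
    b_out = b.subset_markers(np.array(b_keep, dtype=int))
    if b_keep:
        neg = np.array(b_negate)
        b_out.calls[:, neg] = -b_out.calls[:, neg]
        # adopt a's orientation in metadata too
        b_out.markers.loc[neg, ["ref_allele", "alt_allele"]] = (
            b_out.markers.loc[neg, ["alt_allele", "ref_allele"]].to_numpy()
        )
    return a_out, b_out
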