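"""NC II cross enumeration and hybrid genotype deduction.

In a North Carolina II factorial every female parent is mated to every male
tester.  With fully inbred (homozygous) parents the F1 genotype at each
marker is determined exactly: the hybrid of two like homozygotes is that
homozygote, the hybrid of opposite homozygotes is heterozygous.  Residual
parental heterozygosity yields expected dosages (+-0.5), which downstream
additive models accept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix

HYBRID_SEP = "×"  # "×", female first by convention


def hybrid_id(female: str, male: str) -> str:
    return f"{female}{HYBRID_SEP}{male}"


@dataclass
class CrossSet:
    """Ordered list of (female_id, male_id) parent pairs."""

    crosses: list[tuple[str, str]]

    def __post_init__(self):
        if len(set(self.crosses)) != len(self.crosses):
            raise ValueError("duplicate (female, male) pairs in cross set")

    def __len__(self) -> int:
        return len(self.crosses)

    @property
    def hybrid_ids(self) -> list[str]:
        return [hybrid_id(f, m) for f, m in self.crosses]


def enumerate_crosses(females: list[str], males: list[str]) -> CrossSet:
    """Full factorial cross set, female-major then male order."""
    if not females or not males:
        raise ValueError("parent lists must be non-empty")
    if len(set(females)) != len(females):
        raise ValueError("duplicate ids in female list")
    if len(set(males)) != len(males):
        raise ValueError("duplicate ids in male list")
    return CrossSet([(f, m) for f in females for m in males])


def deduce_hybrid_genotypes(parents: GenotypeMatrix, crosses: CrossSet) -> GenotypeMatrix:
    """Deduce F1 genotypes as the mean of the parental codes.

    (+1,+1)->+1, (-1,-1)->-1, opposite homozygotes -> 0; a heterozygous
    parent (code 0) yields the expected dosage +-0.5, flagged with a warning.
    Output sample order equals cross order; hybrids are named "female×male".
    """
    if not parents.is_encoded():
        raise ValueError("parents must be fully encoded (no missing calls)")
    index = {s: i for i, s in enumerate(parents.samples)}
    for f, m in crosses.crosses:
        if f not in index:
            raise KeyError(f"unknown female parent {f!r}")
        if m not in index:
            raise KeyError(f"unknown male parent {m!r}")
    f_rows = np.array([index[f] for f, _ in crosses.crosses])
    m_rows = np.array([index[m] for _, m in crosses.crosses])
    calls = (parents.calls[f_rows] + parents.calls[m_rows]) / 2.0
    if np.any(np.abs(calls) == 0.5):
        warnings.warn(
            "heterozygous parent encountered; hybrid codes include expected "
            "dosages of +-0.5",
            stacklevel=2,
        )
    groups = {h: "hybrid" for h in crosses.hybrid_ids}
    return GenotypeMatrix(crosses.hybrid_ids, parents.markers.copy(), calls, groups)
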