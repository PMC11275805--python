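"""Core identity types shared across the pipeline.

A variant is a single amino-acid substitution in the scanned protein
region, identified by 1-based residue position, wild-type residue,
mutant residue (``*`` for a stop codon) and a class label.  Conditions
are selection environments: the DMSO control or one inhibitor, each
annotated with an inhibitor-type label and the number of wild-type cell
doublings per sampling interval (2 by experimental design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Stop symbol used for nonsense variants.
STOP = "*"

VAR_CLASSES = ("missense", "synonymous", "nonsense")

#: Recognised inhibitor-type labels. ``I_a``/``I_b`` are subtypes of
#: type I (active-conformation binders); ``II`` binds the inactive
#: back-pocket-open conformation; ``I_half`` shares features of both;
#: ``III`` is allosteric.  Exactly one condition per experiment is DMSO.
INHIBITOR_TYPES = ("DMSO", "I_a", "I_b", "II", "I_half", "III")

_MAJOR = {"DMSO": "DMSO", "I_a": "I", "I_b": "I", "II": "II",
          "I_half": "I_half", "III": "III"}


def major_type(inhibitor_type: str) -> str:
    """Collapse subtype labels to the major type used for hotspot
    aggregation (I_a, I_b -> I)."""
    try:
        return _MAJOR[inhibitor_type]
    except KeyError:
        raise ValueError(f"unknown inhibitor type {inhibitor_type!r}") from None


class VariantKey(NamedTuple):
    """Identity of one amino-acid substitution."""

    position: int
    wt_aa: str
    mut_aa: str
    var_class: str

    @classmethod
    def make(cls, position: int, wt_aa: str, mut_aa: str) -> "VariantKey":
        if mut_aa == STOP:
            var_class = "nonsense"
        elif mut_aa == wt_aa:
            var_class = "synonymous"
        else:
            var_class = "missense"
        return cls(int(position), wt_aa, mut_aa, var_class)


VARIANT_COLUMNS = ["position", "wt_aa", "mut_aa", "var_class"]


@dataclass(frozen=True)
class ConditionMeta:
    """One selection condition (DMSO control or inhibitor)."""

    name: str
    inhibitor_type: str
    wt_doublings_per_interval: float = 2.0

    def __post_init__(self) -> None:
        if self.inhibitor_type not in INHIBITOR_TYPES:
            raise ValueError(
                f"inhibitor_type must be one of {INHIBITOR_TYPES}, "
                f"got {self.inhibitor_type!r}")
        if not self.wt_doublings_per_interval > 0:
            raise ValueError("wt_doublings_per_interval must be positive")

    @property
    def is_dmso(self) -> bool:
        return self.inhibitor_type == "DMSO"

    @property
    def major_type(self) -> str:
        return major_type(self.inhibitor_type)


def check_one_dmso(conditions: list[ConditionMeta]) -> None:
    """An experiment carries exactly one DMSO control."""
    n = sum(c.is_dmso for c in conditions)
    if n != 1:
        raise ValueError(f"expected exactly one DMSO condition, found {n}")


@dataclass(frozen=True)
class SimDesign:
    """Replication / sequencing design of a simulated screen.

    ``depth`` is reads per (replicate, timepoint) sample.  With
    ``noise_mode='none'`` the simulator emits real-valued expected
    counts (depth times expected frequency); with ``'multinomial'`` it
    draws integer counts summing exactly to ``depth`` per sample.
    """

    n_replicates: int = 3
    n_timepoints: int = 4
    depth: int = 1_000_000
    noise_mode: str = "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.noise_mode not in ("none", "multinomial"):
            raise ValueError("noise_mode must be 'none' or 'multinomial'")
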