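"""Circulating DNA quantification in haploid genome equivalents.

Plasma cell-free DNA (cfDNA) is measured as a mass concentration (pg/mL);
one haploid genome equivalent (hGE) weighs 3.3 pg, so

    [cfDNA] (hGE/mL) = cfDNA (pg/mL) / 3.3

The tumour-derived fraction (ctDNA) is quantified from the somatic variant
allele frequencies (VAF) of the mutations used for detection calling:

    [ctDNA] (hGE/mL) = mean(VAF) * cfDNA (pg/mL) / 3.3

When no lymphoma mutation is found the ctDNA level is *null* (a false
negative of the assay, not zero): null records stay in the cohort table and
are dropped only inside ctDNA-specific analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError

__all__ = ["HGE_PG", "MutationCall", "BloodDnaRecord", "cfdna_hge", "ctdna_hge", "quantify_cohort"]

#: Mass of one haploid genome equivalent, pg.
HGE_PG = 3.3


@dataclass(frozen=True)
class MutationCall:
    variant_id: str
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"VAF must be in [0, 1], got {self.vaf} for {self.variant_id}")


def cfdna_hge(cfdna_pg_per_ml: float) -> float:
    """Total cfDNA in hGE/mL from its mass concentration in pg/mL."""
    if cfdna_pg_per_ml < 0:
        raise ValidationError(f"cfDNA concentration must be >= 0, got {cfdna_pg_per_ml}")
    return cfdna_pg_per_ml / HGE_PG


def ctdna_hge(mutations: list[MutationCall], cfdna_pg_per_ml: float) -> float | None:
    """ctDNA in hGE/mL, or None when no mutation was found (false negative)."""
    if cfdna_pg_per_ml < 0:
        raise ValidationError(f"cfDNA concentration must be >= 0, got {cfdna_pg_per_ml}")
    if not mutations:
        return None
    mean_vaf = sum(m.vaf for m in mutations) / len(mutations)
    return mean_vaf * cfdna_pg_per_ml / HGE_PG


@dataclass(frozen=True)
class BloodDnaRecord:
    """Per-patient circulating DNA quantification."""

    cfdna_pg_per_ml: float
    mutations: tuple[MutationCall, ...] = field(default_factory=tuple)

    @property
    def cfdna_hge(self) -> float:
        return cfdna_hge(self.cfdna_pg_per_ml)

    @property
    def ctdna_hge(self) -> float | None:
        return ctdna_hge(list(self.mutations), self.cfdna_pg_per_ml)

    @property
    def mean_vaf(self) -> float | None:
        if not self.mutations:
            return None
        return sum(m.vaf for m in self.mutations) / len(self.mutations)


def quantify_cohort(patients: pd.DataFrame, mutations: pd.DataFrame) -> pd.DataFrame:
    """Quantify [cfDNA] and [ctDNA] for a cohort.

    Parameters
    ----------
    patients
        One row per patient with columns ``patient_id`` and
        ``cfdna_pg_per_ml``.
    mutations
        One row per mutation call with columns ``patient_id``,
        ``variant_id`` and ``vaf``.  Patients absent from this table have no
        detected mutation and get a null (NaN) ctDNA.

    Returns
    -------
    DataFrame indexed like ``patients`` with added columns ``cfdna_hge``,
    ``ctdna_hge`` (NaN = no mutation found) and ``n_mutations``.
    """
    required = {"patient_id", "cfdna_pg_per_ml"}
    if not required.issubset(patients.columns):
        raise ValidationError(f"patients table needs columns {sorted(required)}")
    if len(mutations) and not {"patient_id", "vaf"}.issubset(mutations.columns):
        raise ValidationError("mutations table needs columns ['patient_id', 'vaf']")
    if len(mutations):
        bad = mutations[(mutations["vaf"] < 0) | (mutations["vaf"] > 1)]
        if len(bad):
            raise ValidationError(f"VAF outside [0, 1] for patients {sorted(bad['patient_id'].unique())}")
        per_patient = mutations.groupby("patient_id")["vaf"].agg(["mean", "size"])
    else:
        per_patient = pd.DataFrame(columns=["mean", "size"])
    out = patients.copy()
    out["cfdna_hge"] = out["cfdna_pg_per_ml"].map(cfdna_hge)
    mean_vaf = out["patient_id"].map(per_patient["mean"])
    out["n_mutations"] = out["patient_id"].map(per_patient["size"]).fillna(0).astype(int)
    out["ctdna_hge"] = mean_vaf * out["cfdna_pg_per_ml"] / HGE_PG
    return out
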