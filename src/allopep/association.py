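"""Cohort association of alloreactivity estimates with chronic GvHD.

For each estimation method M1-M4 a logistic regression contrasts chronic
GvHD grades "no" (coded 0) versus "extensive" (coded 1) — "limited"
pairs are excluded — with the method's ligand count as the predictor of
interest and confounding covariates: the method-matched total mismatch
count (all mismatched peptides for M1/M3, filtered for M2/M4), the sum
of cohort frequencies of the recipient's unique HLA alleles, the number
of unique HLA alleles, transplantation year, donor age, female-to-male
transplant direction, and the 0-12 HLA allele match count over the six
classical loci.  Numerical predictors are centred and scaled to unit
sample standard deviation so coefficients are comparable across methods.
P-values for each coefficient come from the Wald test; the four
ligand-count p-values are jointly Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .alloreactivity_scoring import HLA_LOCI, HLATyping, MismatchEstimate

logger = logging.getLogger(__name__)

METHODS = ("m1", "m2", "m3", "m4")

#: Covariate label -> whether the method-matched mismatch total is used.
MISMATCH_COVARIATE = {"m1": "total_mismatched", "m2": "total_filtered",
                      "m3": "total_mismatched", "m4": "total_filtered"}

COVARIATE_ORDER = (
    "ligand_count",
    "n_mismatched_peptides",
    "hla_freq_sum",
    "f_to_m",
    "donor_age",
    "n_unique_hla",
    "tr_year",
    "hla_match_count",
)

NUMERIC_COVARIATES = frozenset(COVARIATE_ORDER) - {"f_to_m"}


class AssociationError(ValueError):
    """Degenerate design or failed model fit."""


@dataclass(frozen=True)
class OutcomeRecord:
    """Clinical outcome and pair-level metadata for one transplant pair."""

    pair_id: str
    cgvhd_grade: str  # "no" | "limited" | "extensive"
    donor_age: float
    tr_year: float
    f_to_m: bool
    agvhd_grade: int = 0  # carried, unused
    relapse: bool = False  # carried, unused

    def __post_init__(self) -> None:
        if self.cgvhd_grade not in ("no", "limited", "extensive"):
            raise ValueError(f"{self.pair_id}: bad cGvHD grade {self.cgvhd_grade!r}")


def read_outcomes_tsv(path) -> list[OutcomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    return [
        OutcomeRecord(
            pair_id=row.pair_id,
            cgvhd_grade=row.cgvhd_grade,
            donor_age=float(row.donor_age),
            tr_year=float(row.tr_year),
            f_to_m=bool(row.f_to_m),
            agvhd_grade=int(getattr(row, "agvhd_grade", 0)),
            relapse=bool(getattr(row, "relapse", False)),
        )
        for row in df.itertuples()
    ]


def write_outcomes_tsv(outcomes: list[OutcomeRecord], path) -> None:
    cols = ["pair_id", "cgvhd_grade", "agvhd_grade", "relapse",
            "donor_age", "tr_year", "f_to_m"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for o in sorted(outcomes, key=lambda o: o.pair_id):
            fh.write("\t".join([
                o.pair_id, o.cgvhd_grade, str(o.agvhd_grade),
                str(int(o.relapse)), f"{o.donor_age:g}", f"{o.tr_year:g}",
                str(int(o.f_to_m)),
            ]) + "\n")


# ---------------------------------------------------------------------------
# HLA covariates
# ---------------------------------------------------------------------------

def count_hla_matches(donor: HLATyping, recipient: HLATyping) -> int:
    """Identical alleles over the six loci, 0-12, multiset semantics: a
    donor homozygote against a recipient heterozygote sharing one allele
    contributes 1 at that locus."""
    total = 0
    for locus in HLA_LOCI:
        d = Counter(donor.alleles[locus])
        r = Counter(recipient.alleles[locus])
        total += sum((d & r).values())
    return total


def compute_hla_covariates(
    cohort: list[HLATyping], recipient: HLATyping, *, mode: str = "carrier"
) -> tuple[float, int]:
    """(hla_freq_sum, n_unique_hla) for one recipient against the cohort.

    ``carrier`` mode defines freq(a) as the fraction of cohort recipients
    carrying allele a; ``allele_count`` mode as a's share of all typed
    allele slots.
    """
    if not cohort:
        raise AssociationError("empty cohort")
    distinct = recipient.distinct_alleles()
    if mode == "carrier":
        freqs = {
            a: sum(1 for t in cohort if a in t.distinct_alleles()) / len(cohort)
            for a in distinct
        }
    elif mode == "allele_count":
        counts: Counter = Counter()
        total = 0
        for t in cohort:
            for locus in HLA_LOCI:
                counts.update(t.alleles[locus])
                total += 2
        freqs = {a: counts[a] / total for a in distinct}
    else:
        raise ValueError(f"unknown hla_freq mode {mode!r}")
    return sum(freqs.values()), len(distinct)


def scale_center(values) -> np.ndarray:
    """Centre to mean 0 and scale to unit sample standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise AssociationError("need at least 2 values to scale")
    sd = x.std(ddof=1)
    if sd == 0:
        raise AssociationError("zero spread: cannot scale a constant covariate")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_logistic_wald(
    outcomes, design: pd.DataFrame, *, maxiter: int = 100, tol: float = 1e-8
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit with intercept and Wald inference.

    Returns a DataFrame indexed by term with columns estimate, std_error,
    z_value, p_value.  Raises :class:`AssociationError` on non-convergence
    or separation.
    """
    y = np.asarray(outcomes, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    try:
        result = sm.Logit(y, X).fit(
            disp=False, maxiter=maxiter, tol=tol, warn_convergence=False
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise AssociationError(f"logistic fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise AssociationError(
            "logistic fit did not converge (possible separation); "
            f"final log-likelihood {result.llf:.4g}"
        )
    if np.any(~np.isfinite(result.bse)) or np.any(result.bse > 1e4):
        raise AssociationError("unstable standard errors suggest separation")
    table = pd.DataFrame(
        {
            "estimate": result.params,
            "std_error": result.bse,
            "z_value": result.tvalues,
            "p_value": result.pvalues,
        }
    )
    table.index.name = "variable"
    return table.rename(index={"const": "(Intercept)"})


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------------------
# Association suite (Table-3 analogue)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairCovariates:
    """Non-peptide covariates for one pair, prior to scaling."""

    pair_id: str
    hla_freq_sum: float
    n_unique_hla: int
    tr_year: float
    donor_age: float
    f_to_m: bool
    hla_match_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.hla_match_count <= 12):
            raise ValueError("hla_match_count must be within 0-12")


@dataclass
class AssociationConfig:
    outcome_contrast: tuple[str, str] = ("no", "extensive")
    fdr_threshold: float = 0.05
    methods: tuple[str, ...] = METHODS
    hla_freq_mode: str = "carrier"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass
class AssociationResult:
    """Per-method coefficient tables plus jointly adjusted ligand p-values."""

    tables: dict[str, pd.DataFrame]  # method -> per-covariate Wald table
    ligand_p: dict[str, float]
    ligand_p_adjusted: dict[str, float]
    errors: dict[str, str] = field(default_factory=dict)
    n_no: int = 0
    n_extensive: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: method, variable, estimate, std_error, z, p,
        p_adjusted (adjusted only on the ligand-count rows)."""
        rows = []
        for method, table in self.tables.items():
            for variable, row in table.iterrows():
                rows.append(
                    {
                        "method": method.upper(),
                        "variable": variable,
                        "estimate": row["estimate"],
                        "std_error": row["std_error"],
                        "z_value": row["z_value"],
                        "p_value": row["p_value"],
                        "p_adjusted": self.ligand_p_adjusted.get(method)
                        if variable == "ligand_count"
                        else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def build_design(
    estimates: dict[str, MismatchEstimate],
    covariates: dict[str, PairCovariates],
    outcomes: list[OutcomeRecord],
    method: str,
    config: AssociationConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble (outcome vector, scaled design matrix) for one method,
    excluding pairs outside the configured outcome contrast."""
    lo, hi = config.outcome_contrast
    kept = [o for o in outcomes if o.cgvhd_grade in (lo, hi)]
    missing = [o.pair_id for o in kept
               if o.pair_id not in estimates or o.pair_id not in covariates]
    if missing:
        raise AssociationError(f"missing estimates/covariates for pairs {missing[:5]}")
    y = np.array([1.0 if o.cgvhd_grade == hi else 0.0 for o in kept])
    if len(set(y)) < 2:
        raise AssociationError(
            f"only one outcome class present after excluding grades outside "
            f"{config.outcome_contrast}"
        )
    mismatch_field = MISMATCH_COVARIATE[method]
    unavailable = [
        o.pair_id for o in kept
        if getattr(estimates[o.pair_id], method) is None
        or getattr(estimates[o.pair_id], mismatch_field) is None
    ]
    if unavailable:
        raise AssociationError(
            f"method {method}: filtered counts unavailable for "
            f"{len(unavailable)} pair(s) (no expression table?)"
        )
    raw = pd.DataFrame(
        {
            "ligand_count": [getattr(estimates[o.pair_id], method) for o in kept],
            "n_mismatched_peptides": [
                getattr(estimates[o.pair_id], mismatch_field) for o in kept
            ],
            "hla_freq_sum": [covariates[o.pair_id].hla_freq_sum for o in kept],
            "f_to_m": [float(covariates[o.pair_id].f_to_m) for o in kept],
            "donor_age": [covariates[o.pair_id].donor_age for o in kept],
            "n_unique_hla": [covariates[o.pair_id].n_unique_hla for o in kept],
            "tr_year": [covariates[o.pair_id].tr_year for o in kept],
            "hla_match_count": [
                float(covariates[o.pair_id].hla_match_count) for o in kept
            ],
        },
        index=[o.pair_id for o in kept],
    )
    design = raw.copy()
    for col in list(design.columns):
        if col not in NUMERIC_COVARIATES:
            continue
        values = design[col].to_numpy(dtype=float)
        if values.std(ddof=1) == 0:
            if col == "ligand_count":
                raise AssociationError(
                    f"method {method}: ligand count is constant across pairs"
                )
            # a covariate without variation carries no information; drop it
            logger.warning("dropping constant covariate %r from method %s",
                           col, method)
            design = design.drop(columns=[col])
            continue
        design[col] = scale_center(values)
    return y, design


def run_association_suite(
    estimates: list[MismatchEstimate],
    covariates: dict[str, PairCovariates],
    outcomes: list[OutcomeRecord],
    config: AssociationConfig = AssociationConfig(),
) -> AssociationResult:
    """Fit one logistic model per method and BH-adjust the ligand-count
    p-values jointly across methods.  Per-method fit failures are recorded
    and the remaining methods still run."""
    est_by_pair = {e.pair_id: e for e in estimates}
    tables: dict[str, pd.DataFrame] = {}
    ligand_p: dict[str, float] = {}
    errors: dict[str, str] = {}
    for method in config.methods:
        try:
            y, design = build_design(est_by_pair, covariates, outcomes, method, config)
            tables[method] = fit_logistic_wald(y, design)
            ligand_p[method] = float(tables[method].loc["ligand_count", "p_value"])
        except AssociationError as exc:
            logger.error("method %s: %s", method, exc)
            errors[method] = str(exc)
    adjusted = bh_adjust(list(ligand_p.values()))
    lo, hi = config.outcome_contrast
    return AssociationResult(
        tables=tables,
        ligand_p=ligand_p,
        ligand_p_adjusted=dict(zip(ligand_p, adjusted)),
        errors=errors,
        n_no=sum(1 for o in outcomes if o.cgvhd_grade == lo),
        n_extensive=sum(1 for o in outcomes if o.cgvhd_grade == hi),
    )
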