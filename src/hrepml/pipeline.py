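"""End-to-end association run: kinship -> spectral -> scan -> screen -> PML -> calls."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from hrepml import kinship as kin
from hrepml import pml, reml
from hrepml.io_formats import (
    CovariateTable,
    DimensionError,
    GenotypeTable,
    KinshipTable,
    PhenotypeVector,
    ResultRecord,
)

__all__ = ["AssociationConfig", "AssociationResult", "run_association"]


@dataclass
class AssociationConfig:
    """Tuning knobs of the two-stage run.

    ``p_cutoff`` is the loose single-locus screening threshold, ``tau`` the
    shrinkage hyperparameter of the multi-locus stage, ``lod_cutoff`` the
    final call threshold.  ``cap_survivors`` keeps at most n - c - 1
    screened markers (smallest p first) so the joint model stays
    overdetermined.  ``kinship_mode`` selects the literal (uncentered) or
    centered relatedness matrix when the kinship is computed from genotypes.
    """

    p_cutoff: float = 0.01
    tau: float = 1.0
    lod_cutoff: float = 3.0
    tol: float = 1e-6
    max_iter: int = 200
    kinship_mode: str = "literal"
    cap_survivors: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff <= 1.0:
            raise ValueError("p_cutoff must lie in (0, 1]")
        if self.lod_cutoff <= 0.0:
            raise ValueError("lod_cutoff must be positive")
        if self.kinship_mode not in ("literal", "centered"):
            raise ValueError("kinship_mode must be 'literal' or 'centered'")


@dataclass
class AssociationResult:
    """Everything the run produced, from scan fits to final records."""

    records: list[ResultRecord]
    selected_markers: np.ndarray
    screened_markers: np.ndarray
    fits: list[reml.MarkerFit]
    null_fit: reml.NullFit
    pml_state: pml.PMLState | None
    pml_result: pml.PMLResult | None
    timings: dict[str, float] = field(default_factory=dict)


def _check_dimensions(G: GenotypeTable, y, F, K) -> None:
    n = G.sample_count
    if len(y) != n:
        raise DimensionError(
            f"phenotype length {len(y)} does not match genotype sample count {n}"
        )
    if F is not None and F.sample_count != n:
        raise DimensionError(
            f"covariate rows {F.sample_count} do not match genotype sample count {n}"
        )
    if K is not None and K.sample_count != n:
        raise DimensionError(
            f"kinship dimension {K.sample_count} does not match genotype sample count {n}"
        )


def run_association(
    genotype: GenotypeTable,
    phenotype,
    covariates: CovariateTable | None = None,
    kinship: KinshipTable | None = None,
    config: AssociationConfig | None = None,
) -> AssociationResult:
    """Run the full two-stage association pipeline in memory.

    When no kinship is supplied it is computed from the genotypes; when no
    covariates are given an intercept-only design is used.  Returns a result
    whose ``records`` list one row per finally declared marker (possibly
    empty) in genome order.
    """
    config = config or AssociationConfig()
    y = phenotype if isinstance(phenotype, PhenotypeVector) else PhenotypeVector(np.asarray(phenotype))
    if covariates is None:
        covariates = CovariateTable(np.ones((genotype.sample_count, 1)))
    _check_dimensions(genotype, y, covariates, kinship)

    timings: dict[str, float] = {}
    tic = time.perf_counter()
    if kinship is None:
        kinship = kin.compute_kinship(genotype, centered=(config.kinship_mode == "centered"))
    timings["kinship"] = time.perf_counter() - tic

    tic = time.perf_counter()
    basis = kin.spectral_decompose(kinship)
    kin.rotate(y.values, covariates.design, basis)
    timings["spectral"] = time.perf_counter() - tic

    tic = time.perf_counter()
    null_fit = reml.fit_null(basis.rotated_phenotype, basis.rotated_covariates, basis.eigenvalues)
    context = reml.ScanContext(basis=basis, null=null_fit)
    fits = reml.scan(genotype, context)
    timings["scan"] = time.perf_counter() - tic

    tic = time.perf_counter()
    cap = genotype.sample_count - covariates.count - 1 if config.cap_survivors else None
    screened = reml.screen_markers(fits, config.p_cutoff, max_survivors=cap)
    timings["screen"] = time.perf_counter() - tic

    records: list[ResultRecord] = []
    selected = np.array([], dtype=int)
    state = None
    result = None
    tic = time.perf_counter()
    if screened.size:
        X_sub = genotype.sample_major()[:, screened]
        state = pml.fit_pml(
            y.values,
            covariates.design,
            X_sub,
            tau=config.tau,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        result = pml.select_markers(
            state, y.values, covariates.design, X_sub, lod_cutoff=config.lod_cutoff
        )
        selected = screened[result.selected]
        order = np.argsort(selected)
        selected = selected[order]
        for rank in order:
            marker = screened[result.selected[rank]]
            records.append(
                ResultRecord(
                    chromosome=int(genotype.chromosome[marker]),
                    position=int(genotype.position[marker]),
                    effect=float(result.effects[rank]),
                    std_error=float(result.std_errors[rank]),
                    lod=float(result.lod[rank]),
                )
            )
    timings["pml"] = time.perf_counter() - tic

    return AssociationResult(
        records=records,
        selected_markers=selected,
        screened_markers=screened,
        fits=fits,
        null_fit=null_fit,
        pml_state=state,
        pml_result=result,
        timings=timings,
    )
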