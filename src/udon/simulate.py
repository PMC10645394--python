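"""Synthetic multi-patient, multi-cell-type cohorts with planted programs.

The generator emulates the structure the pipeline assumes rather than raw
sequencing reality: per-cell expression is simulated directly on the log
scale as gene baseline + cell-type offset + planted program effect +
Gaussian noise.  Disease *programs* are coherent log-fold shifts of a gene
block confined to chosen (member sample, member cell type) combinations,
and binary covariates can be linked to a program's member samples with a
small label-flip probability.  Ground truth (program membership per
pseudobulk column and per covariate) is returned alongside, so recovery
can be scored end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CONTROL, DISEASE, CellCohort
from .errors import InputError
from .pseudobulk import column_name
from .satay import CovariateTable


@dataclass
class ProgramSpec:
    """One planted disease program."""

    gene_count: int = 40
    effect_size: float = 1.5          # mean log-fold shift of program genes
    member_samples: tuple = ()        # disease sample names carrying the program
    member_cell_types: tuple = ()     # cell types in which it is expressed


@dataclass
class CovariateSpec:
    """One binary covariate, optionally tied to a program's member samples."""

    name: str
    linked_program: int | None = None  # index into SimSpec.programs, or None
    flip_prob: float = 0.05


@dataclass
class SimSpec:
    """Cohort-level simulation parameters (defaults = study conditions)."""

    n_disease_samples: int = 16
    n_control_samples: int = 5
    n_cell_types: int = 8
    cells_per_type_per_sample: tuple = (30, 200)
    n_genes: int = 2000
    programs: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    base_loc: float = 0.0             # lognormal location of per-gene baselines
    base_scale: float = 0.5           # lognormal scale of per-gene baselines
    cell_type_offset_sd: float = 0.5  # per-(gene, cell type) baseline spread
    noise_sd: float = 0.4             # per-cell Gaussian noise on the log scale
    seed: int = 0

    @property
    def disease_samples(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_disease_samples)]

    @property
    def control_samples(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_control_samples)]

    @property
    def cell_types(self) -> list[str]:
        return [f"ct{j + 1}" for j in range(self.n_cell_types)]

    @property
    def genes(self) -> list[str]:
        return [f"g{g + 1:04d}" for g in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted structure: program membership per pseudobulk column and gene."""

    program_genes: dict            # program index -> list of genes
    program_columns: dict          # program index -> list of "sample|celltype" columns
    column_program: pd.Series      # column -> program index (planted columns only)
    covariate_truth: pd.DataFrame  # sample x covariate, noise-free values

    def to_json(self) -> str:
        return json.dumps({
            "program_genes": {str(k): list(v) for k, v in self.program_genes.items()},
            "program_columns": {str(k): list(v) for k, v in self.program_columns.items()},
            "column_program": {str(c): int(p) for c, p in self.column_program.items()},
            "covariate_truth": self.covariate_truth.to_dict(),
        }, indent=2, sort_keys=True)


def default_spec(n_programs: int = 5, seed: int = 0, *, samples_per_program: int = 5,
                 link_covariates: bool = True, **overrides) -> SimSpec:
    """The standard well-separated cohort: disjoint program blocks.

    Program p occupies its own cell type (so planted columns never overlap)
    and a seeded random subset of disease samples; each program gets one
    linked covariate when ``link_covariates``.
    """
    spec = SimSpec(seed=seed, **overrides)
    if n_programs > spec.n_cell_types:
        raise InputError("need at least one distinct cell type per program")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(901,)))
    gene_cursor = 0
    for p in range(n_programs):
        members = rng.choice(spec.disease_samples, size=samples_per_program, replace=False)
        prog = ProgramSpec(member_samples=tuple(sorted(members)),
                           member_cell_types=(spec.cell_types[p],))
        spec.programs.append(prog)
        gene_cursor += prog.gene_count
        if gene_cursor > spec.n_genes:
            raise InputError("program gene blocks exceed n_genes")
        if link_covariates:
            spec.covariates.append(CovariateSpec(name=f"cov_prog{p + 1}", linked_program=p))
    return spec


def null_spec(seed: int = 0, n_covariates: int = 3, **overrides) -> SimSpec:
    """A cohort with no planted programs and covariates independent of everything."""
    spec = SimSpec(seed=seed, **overrides)
    for i in range(n_covariates):
        spec.covariates.append(CovariateSpec(name=f"cov_null{i + 1}", linked_program=None,
                                             flip_prob=0.5))
    return spec


# ----------------------------------------------------------------------
def simulate_cohort(spec: SimSpec) -> tuple[CellCohort, CovariateTable, GroundTruth]:
    """Draw a cohort, its covariates and the planted ground truth.

    Deterministic given ``spec.seed``: the same spec yields bitwise
    identical outputs.
    """
    _validate_spec(spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))

    genes = spec.genes
    cell_types = spec.cell_types
    samples = spec.disease_samples + spec.control_samples
    conditions = [DISEASE] * spec.n_disease_samples + [CONTROL] * spec.n_control_samples

    baseline = rng.lognormal(mean=spec.base_loc, sigma=spec.base_scale, size=spec.n_genes)
    ct_offset = rng.normal(0.0, spec.cell_type_offset_sd,
                           size=(spec.n_genes, spec.n_cell_types))

    # assign disjoint gene blocks to programs in declaration order
    program_genes: dict[int, list[str]] = {}
    cursor = 0
    for p, prog in enumerate(spec.programs):
        program_genes[p] = genes[cursor: cursor + prog.gene_count]
        cursor += prog.gene_count

    lo, hi = spec.cells_per_type_per_sample
    blocks, cell_ids, obs_rows = [], [], []
    counter = 0
    for sample, condition in zip(samples, conditions):
        for j, ct in enumerate(cell_types):
            n = int(rng.integers(lo, hi + 1))
            mean = baseline + ct_offset[:, j]
            effect = np.zeros(spec.n_genes)
            for p, prog in enumerate(spec.programs):
                if sample in prog.member_samples and ct in prog.member_cell_types:
                    gidx = slice(sum(pr.gene_count for pr in spec.programs[:p]),
                                 sum(pr.gene_count for pr in spec.programs[: p + 1]))
                    effect[gidx] += prog.effect_size
            cells = mean[:, None] + effect[:, None] + rng.normal(
                0.0, spec.noise_sd, size=(spec.n_genes, n))
            blocks.append(cells)
            ids = [f"cell{counter + i:06d}" for i in range(n)]
            counter += n
            cell_ids.extend(ids)
            obs_rows.extend({"sample": sample, "cell_type": ct} for _ in ids)

    expression = pd.DataFrame(np.concatenate(blocks, axis=1), index=pd.Index(genes),
                              columns=pd.Index(cell_ids))
    obs = pd.DataFrame(obs_rows, index=pd.Index(cell_ids))
    sample_meta = pd.DataFrame({"condition": conditions}, index=pd.Index(samples))
    cohort = CellCohort(expression=expression, obs=obs, sample_meta=sample_meta)

    # covariates
    cov_rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    truth_cols, noisy_cols = {}, {}
    for cov in spec.covariates:
        if cov.linked_program is not None:
            members = set(spec.programs[cov.linked_program].member_samples)
            truth = np.array([1 if s in members else 0 for s in samples])
        else:
            truth = np.zeros(len(samples), dtype=int)
        flips = cov_rng.random(len(samples)) < cov.flip_prob
        noisy_cols[cov.name] = np.where(flips, 1 - truth, truth)
        truth_cols[cov.name] = truth
    if spec.covariates:
        cov_values = pd.DataFrame(noisy_cols, index=pd.Index(samples), dtype=float)
        covariate_truth = pd.DataFrame(truth_cols, index=pd.Index(samples))
    else:
        cov_values = pd.DataFrame({"cov_dummy": np.zeros(len(samples))},
                                  index=pd.Index(samples))
        covariate_truth = cov_values.astype(int)
    covariates = CovariateTable(values=cov_values)

    program_columns = {
        p: [column_name(s, ct) for s in prog.member_samples for ct in prog.member_cell_types]
        for p, prog in enumerate(spec.programs)
    }
    col_prog = {}
    for p, cols in program_columns.items():
        for c in cols:
            col_prog[c] = p
    truth = GroundTruth(
        program_genes=program_genes,
        program_columns=program_columns,
        column_program=pd.Series(col_prog, dtype=int),
        covariate_truth=covariate_truth,
    )
    return cohort, covariates, truth


def _validate_spec(spec: SimSpec) -> None:
    if spec.n_disease_samples < 1 or spec.n_control_samples < 1:
        raise InputError("cohort needs at least one disease and one control sample")
    if sum(p.gene_count for p in spec.programs) > spec.n_genes:
        raise InputError("program gene blocks exceed n_genes")
    known_ct = set(spec.cell_types)
    known_samples = set(spec.disease_samples)
    for p, prog in enumerate(spec.programs):
        if not set(prog.member_cell_types) <= known_ct:
            raise InputError(f"program {p} references unknown cell types")
        if not set(prog.member_samples) <= known_samples:
            raise InputError(f"program {p} member samples must be disease samples")
    for cov in spec.covariates:
        if cov.linked_program is not None and not 0 <= cov.linked_program < len(spec.programs):
            raise InputError(f"covariate '{cov.name}' references unknown program")


def simulate_null_association_design(seed: int = 0, *, n_samples: int = 20,
                                     n_cell_types: int = 4, n_clusters: int = 4,
                                     n_covariates: int = 3
                                     ) -> tuple[pd.DataFrame, CovariateTable]:
    """Cluster labels and covariates drawn independently of each other.

    A label-level null for the association stage: every (sample, cell type)
    pseudobulk gets a uniform random cluster, every sample a Bernoulli(1/2)
    covariate, with no coupling.  Any association flagged on this design is
    a false positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    cell_types = [f"ct{j + 1}" for j in range(n_cell_types)]
    rows = []
    for s in samples:
        for ct in cell_types:
            rows.append({"sample": s, "cell_type": ct,
                         "cluster": f"U{rng.integers(1, n_clusters + 1)}"})
    labels = pd.DataFrame(rows, index=pd.Index(
        [column_name(r["sample"], r["cell_type"]) for r in rows]))
    values = pd.DataFrame(
        rng.integers(0, 2, size=(n_samples, n_covariates)).astype(float),
        index=pd.Index(samples), columns=[f"cov{i + 1}" for i in range(n_covariates)])
    return labels, CovariateTable(values=values)


# ----------------------------------------------------------------------
def make_fixture_suite(out_dir, seed: int = 0, **size_overrides) -> dict:
    """Write three canned cohorts (null / separated / confounded) to disk.

    Each cohort is stored in the package's standard file formats (dense
    expression TSV, annotation TSV, covariate TSV) plus a ground-truth
    sidecar JSON.  ``size_overrides`` (e.g. ``n_genes=400``) shrink the
    cohorts for quick round-trip checks.  Returns {name: directory}.
    """
    from . import io as udon_io

    out = Path(out_dir)
    written = {}
    scenarios = {
        "null": null_spec(seed=seed, **size_overrides),
        "separated": default_spec(seed=seed, **size_overrides),
        "confounded": confounded_spec(seed=seed, **size_overrides),
    }
    for name, spec in scenarios.items():
        d = out / name
        d.mkdir(parents=True, exist_ok=True)
        cohort, covariates, truth = simulate_cohort(spec)
        udon_io.write_cohort_tsv(cohort, d)
        if name == "confounded":
            covariates = confounded_covariates(spec)
        udon_io.write_covariates_tsv(covariates, d / "covariates.tsv")
        (d / "ground_truth.json").write_text(truth.to_json() + "\n")
        (d / "sim_spec.json").write_text(json.dumps(asdict(spec), indent=2, default=list) + "\n")
        written[name] = d
    return written


def confounded_spec(seed: int = 0, **overrides) -> SimSpec:
    """Cohort whose covariate is driven entirely by a stratum, not a program.

    Samples split into two strata (think: age groups); the planted
    program's members all come from stratum A and the covariate marks
    stratum A membership, not program membership.  An unstratified Fisher
    test sees an association that CMH, stratified on the confounder,
    explains away.  Strata come from :func:`confounder_strata`.
    """
    spec = SimSpec(seed=seed, **overrides)
    strata = confounder_strata(spec)
    stratum_a = [s for s in spec.disease_samples if strata[s] == "stratumA"]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(902,)))
    members = tuple(sorted(rng.choice(stratum_a, size=min(5, len(stratum_a)), replace=False)))
    spec.programs.append(ProgramSpec(member_samples=members,
                                     member_cell_types=(spec.cell_types[0],)))
    # a second, stratum-balanced program provides contrast for marker
    # validation without touching the confounded cell type
    others = tuple(sorted(rng.choice(spec.disease_samples, size=5, replace=False)))
    spec.programs.append(ProgramSpec(member_samples=others,
                                     member_cell_types=(spec.cell_types[1],)))
    # covariate = stratum indicator (noise-free), independent of the program
    # conditional on stratum
    spec.covariates.append(CovariateSpec(name="cov_confounded", linked_program=None,
                                         flip_prob=0.0))
    return spec


def confounder_strata(spec: SimSpec) -> pd.Series:
    """Deterministic two-level stratum labels (first half of each arm = A)."""
    values = {}
    for arm in (spec.disease_samples, spec.control_samples):
        half = len(arm) // 2
        for i, s in enumerate(arm):
            values[s] = "stratumA" if i < half else "stratumB"
    return pd.Series(values, name="stratum")


def confounded_covariates(spec: SimSpec) -> CovariateTable:
    """Covariate table for :func:`confounded_spec`: stratum-A indicator."""
    strata = confounder_strata(spec)
    samples = spec.disease_samples + spec.control_samples
    values = pd.DataFrame(
        {"cov_confounded": [1.0 if strata[s] == "stratumA" else 0.0 for s in samples]},
        index=pd.Index(samples))
    return CovariateTable(values=values, strata=strata)
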