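"""Config-driven end-to-end runs: simulate/read -> design -> effects -> tables.

A run is described by one :class:`RunConfig` (serializable to/from YAML).
All randomness flows from a single master seed through named substreams
(simulation, solver, bootstrap), so a manifest plus the package suffices
to replay a run byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .balance import assert_balance, balance_frame, balance_table, format_table
from .cardinality import BalanceSpec
from .cohort import DEFAULT_OUTCOMES, read_cohort, write_cohort
from .design import run_design
from .effects import BootstrapConfig, effects_frame, format_effects, pipeline_bootstrap
from .pairing import PairingConfig
from .simulate import scenario, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One reproducible analysis run."""

    input_path: str | None = None
    scenario: str | None = "paper-like"
    n_patients: int = 10_000
    balance: BalanceSpec = field(default_factory=BalanceSpec)
    propensity_covariates: list[str] | None = None
    pairing: PairingConfig = field(default_factory=PairingConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    subgroup: tuple[str, object] | None = None  # (column, value)
    outdir: str = "cardmatch-run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("exactly one of input_path / scenario must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "balance" in kwargs:
            kwargs["balance"] = BalanceSpec(**kwargs["balance"])
        if "pairing" in kwargs:
            kwargs["pairing"] = PairingConfig(**kwargs["pairing"])
        if "bootstrap" in kwargs:
            kwargs["bootstrap"] = BootstrapConfig(**kwargs["bootstrap"])
        if kwargs.get("subgroup") is not None:
            col, val = kwargs["subgroup"]
            kwargs["subgroup"] = (col, val)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("subgroup") is not None:
            d["subgroup"] = list(d["subgroup"])
        return d


def _spawn_seeds(master: int, n: int) -> list[int]:
    """Named substream seeds derived from the master seed (all < 2^31)."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(master).spawn(n)]


class PipelineError(RuntimeError):
    """A categorized pipeline failure (bad input, empty match, bootstrap)."""

    def __init__(self, category: str, message: str):
        super().__init__(f"[{category}] {message}")
        self.category = category


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run and write its artifact directory.

    Writes pre-match balance, match result, post-match balance, pair list,
    effects table and a machine-readable manifest; returns the directory.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed, solver_seed, boot_seed = _spawn_seeds(config.seed, 3)

    if config.input_path is not None:
        try:
            cohort = read_cohort(config.input_path)
        except Exception as exc:
            raise PipelineError("input", f"cannot read cohort: {exc}") from exc
        truth = None
    else:
        params = scenario(config.scenario, n_patients=config.n_patients, seed=sim_seed)
        cohort, truth = generate_cohort(params)
        write_cohort(cohort, outdir / "cohort.csv")

    outcomes = list(DEFAULT_OUTCOMES)
    if config.subgroup is not None:
        col, val = config.subgroup
        if col not in cohort.columns:
            raise PipelineError("input", f"subgroup column {col!r} not in cohort")
        cohort = cohort.loc[cohort[col] == val].reset_index(drop=True)
        # the subgrouping variable is no longer an outcome of interest
        outcomes = [o for o in outcomes if o != col]
        logger.info("subgroup %s=%r: %d patients", col, val, len(cohort))

    pre = balance_table(cohort, "all")
    balance_frame(pre).to_csv(outdir / "pre_balance.csv", index=False)
    (outdir / "pre_balance.txt").write_text(format_table(pre, "Pre-match balance"))

    design = run_design(
        cohort, config.balance, config.propensity_covariates, config.pairing,
        seed=solver_seed,
    )
    match = design.match
    logger.info("cardinality %d (status %s); bootstrap replicates %d",
                match.cardinality, match.solver_status, config.bootstrap.n_replicates)
    (outdir / "match.json").write_text(json.dumps(match.to_dict(), sort_keys=True))
    if design.pairs is None:
        raise PipelineError("match", "cardinality match is empty under these constraints")

    post = balance_table(cohort, (match.selected_treated, match.selected_control))
    balance_frame(post).to_csv(outdir / "post_balance.csv", index=False)
    (outdir / "post_balance.txt").write_text(format_table(post, "Post-match balance"))
    report = assert_balance(post, config.balance, reference_sd=match.reference_sd)
    if not report.passed:
        logger.warning("post-match balance check failed: %s", report.failures)

    design.pairs.to_frame(design.fit, design.distances).to_csv(
        outdir / "pairs.csv", index=False
    )

    try:
        estimates = pipeline_bootstrap(
            cohort, config.balance, config.propensity_covariates, config.pairing,
            replace(config.bootstrap, seed=boot_seed), outcomes,
        )
    except RuntimeError as exc:
        raise PipelineError("bootstrap", str(exc)) from exc
    effects_frame(estimates).to_csv(outdir / "effects.csv", index=False)
    (outdir / "effects.txt").write_text(
        format_effects(estimates, "Matched effect estimates")
    )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seeds": {"master": config.seed, "simulation": sim_seed,
                  "solver": solver_seed, "bootstrap": boot_seed},
        "cardinality": match.cardinality,
        "solver_status": match.solver_status,
        "balance_passed": report.passed,
        "bootstrap_replicates": config.bootstrap.n_replicates,
        "true_effects": truth.true_effects if truth is not None else None,
        "realized_treated_fraction": (
            truth.realized_treated_fraction if truth is not None else None),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return outdir
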