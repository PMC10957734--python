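"""Whole-study orchestration: bidirectional univariable MR with the full
sensitivity suite, one-covariate-at-a-time multivariable MR, and a
mediation screen, emitting a machine-readable report.

The per-direction workflow is: genome-wide-significance selection ->
LD clumping -> harmonization -> instrument strength (F) -> IVW /
weighted median / MR-Egger -> Cochran's Q -> Egger intercept test ->
MR-PRESSO (with outlier-corrected re-estimate when triggered) ->
leave-one-out -> significance verdict.  The verdict follows a triple
rule: (a) IVW p below 0.05 divided by the number of outcome traits,
(b) the three estimators agree in sign, and (c) neither the Egger
intercept test nor the PRESSO global test signals pleiotropy (both
p > 0.05).  Every SNP-count change between stages is logged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (MrEstimate, ivw, leave_one_out, mr_egger,
                         weighted_median)
from .exceptions import ConfigurationError, FormatError, InstrumentSelectionError
from .gwas_io import harmonize, read_summary_table
from .instruments import clump, instrument_strength, select_instruments
from .mvmr import build_mvmr_dataset, mvmr_ivw, run_mediation
from .presso import presso

__all__ = [
    "AnalysisConfig", "Verdict", "DirectionResult", "StudyReport",
    "assess_significance", "run_univariable", "run_full_study",
    "load_manifest", "validate_report",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and seeds for one study run."""

    seed: int
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    n_boot: int = 1000
    n_sim: int = 1000
    palindrome_policy: str = "conservative"
    eaf_threshold: float = 0.42
    n_outcomes: int = 2
    alpha: float = 0.05
    random_effects: str = "multiplicative"
    level: float = 0.95
    beta2_method: str = "mvmr"

    def child_seeds(self, n: int) -> list[int]:
        state = np.random.SeedSequence(self.seed).generate_state(n, dtype=np.uint32)
        return [int(s % (2 ** 31)) for s in state]


@dataclass(frozen=True)
class Verdict:
    """Triple significance rule, each criterion stored separately."""

    significant: bool
    pval_pass: bool
    direction_pass: bool
    pleiotropy_pass: bool
    bonferroni_threshold: float


def assess_significance(ivw_p: float, estimate_betas, egger_intercept_p: float,
                        presso_global_p: float, n_outcomes: int = 2) -> Verdict:
    """Apply the triple rule to stored statistics (a pure function).

    significant iff ivw_p < 0.05/n_outcomes (strict), all estimator betas
    share one sign, and both pleiotropy tests have p > 0.05 (strict).
    """
    threshold = 0.05 / n_outcomes
    pval_pass = bool(ivw_p < threshold)
    signs = np.sign(np.asarray(list(estimate_betas), dtype=float))
    direction_pass = bool(len(signs) > 0 and np.all(signs == signs[0]) and signs[0] != 0)
    pleiotropy_pass = bool(egger_intercept_p > 0.05 and presso_global_p > 0.05)
    return Verdict(
        significant=pval_pass and direction_pass and pleiotropy_pass,
        pval_pass=pval_pass, direction_pass=direction_pass,
        pleiotropy_pass=pleiotropy_pass, bonferroni_threshold=threshold)


def _estimate_dict(est: MrEstimate) -> dict:
    return {
        "method": est.method, "beta": est.beta, "se": est.se, "pval": est.pval,
        "n_snps": est.n_snps, "or": est.or_ci.odds_ratio,
        "or_ci_low": est.or_ci.ci_low, "or_ci_high": est.or_ci.ci_high,
    }


@dataclass
class DirectionResult:
    """Everything computed for one exposure->outcome direction."""

    name: str
    stage_log: list = field(default_factory=list)
    estimates: dict = field(default_factory=dict)
    heterogeneity: dict = field(default_factory=dict)
    strength: dict = field(default_factory=dict)
    presso: dict = field(default_factory=dict)
    leave_one_out: dict = field(default_factory=dict)
    verdict: dict = field(default_factory=dict)
    error: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def run_univariable(exposure_table: pd.DataFrame, outcome_table: pd.DataFrame,
                    ld_matrix: pd.DataFrame | None, config: AnalysisConfig,
                    name: str = "exposure->outcome") -> DirectionResult:
    """Run the full univariable workflow for one direction."""
    res = DirectionResult(name=name)
    log = res.stage_log
    wm_seed, presso_seed = config.child_seeds(2)

    selected = select_instruments(exposure_table, config.p_threshold)
    log.append({"stage": "select", "n_snps": len(selected)})
    if ld_matrix is not None:
        clumped = clump(selected, ld_matrix, r2_threshold=config.r2_threshold,
                        window_kb=config.window_kb)
    else:
        clumped = selected  # caller asserts instruments are independent
    log.append({"stage": "clump", "n_snps": len(clumped),
                "skipped": ld_matrix is None})
    h = harmonize(clumped, outcome_table,
                  palindrome_policy=config.palindrome_policy,
                  eaf_threshold=config.eaf_threshold)
    log.append({"stage": "harmonize", "n_snps": h.n_snps,
                "actions": h.action_counts()})

    kept = clumped[clumped["snp_id"].isin(h.data["snp_id"])]
    strength = instrument_strength(kept)
    res.strength = asdict(strength)

    ivw_est, het = ivw(h, random_effects=config.random_effects, level=config.level)
    wm_est = weighted_median(h, n_boot=config.n_boot, seed=wm_seed, level=config.level)
    egger_est, egger_het = mr_egger(h, level=config.level)
    res.estimates = {
        "ivw": _estimate_dict(ivw_est),
        "weighted_median": _estimate_dict(wm_est),
        "mr_egger": _estimate_dict(egger_est),
    }
    res.heterogeneity = {
        "q_stat": het.q_stat, "q_df": het.df, "q_pval": het.pval,
        "egger_intercept": egger_het.egger_intercept,
        "egger_intercept_se": egger_het.egger_intercept_se,
        "egger_intercept_pval": egger_het.egger_intercept_pval,
    }

    pres = presso(h, n_sim=config.n_sim, seed=presso_seed, alpha=config.alpha)
    res.presso = {
        "rss_obs": pres.rss_obs, "global_pval": pres.global_pval,
        "n_sim": pres.n_sim, "outliers": pres.outliers,
        "corrected_estimate": (_estimate_dict(pres.corrected_estimate)
                               if pres.corrected_estimate else None),
    }
    if pres.corrected_estimate is not None:
        log.append({"stage": "presso_correction",
                    "n_snps": pres.corrected_estimate.n_snps,
                    "removed": pres.removed_snps})

    loo = leave_one_out(h, random_effects=config.random_effects, level=config.level)
    res.leave_one_out = {
        "influential": [str(s) for s in loo.influential],
        "max_abs_shift": float(np.max(np.abs(loo.table["beta"] - loo.full.beta))),
        "estimates": loo.table.to_dict(orient="list"),
    }

    verdict = assess_significance(
        ivw_est.pval, [ivw_est.beta, wm_est.beta, egger_est.beta],
        egger_het.egger_intercept_pval, pres.global_pval, config.n_outcomes)
    res.verdict = asdict(verdict)
    return res


@dataclass
class StudyReport:
    """Aggregated study output; serializable to JSON plus flat TSV tables."""

    provenance: dict
    univariable: dict = field(default_factory=dict)   # outcome -> {forward, reverse}
    mvmr: list = field(default_factory=list)
    mediation: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "univariable": self.univariable,
            "mvmr": self.mvmr,
            "mediation": self.mediation,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def table1(self) -> pd.DataFrame:
        rows = []
        for outcome, directions in self.univariable.items():
            for direction, res in directions.items():
                if res.get("error"):
                    continue
                for method in ("ivw", "weighted_median", "mr_egger"):
                    est = res["estimates"][method]
                    rows.append({
                        "outcome": outcome, "direction": direction,
                        "n_snp": est["n_snps"],
                        "f_stat": res["strength"]["f_stat"], "method": method,
                        "or": est["or"], "or_ci_low": est["or_ci_low"],
                        "or_ci_high": est["or_ci_high"], "pval": est["pval"],
                        "heterogeneity_pval": res["heterogeneity"]["q_pval"],
                        "egger_intercept_pval": res["heterogeneity"]["egger_intercept_pval"],
                        "presso_global_pval": res["presso"]["global_pval"],
                        "significant": res["verdict"]["significant"],
                    })
        return pd.DataFrame(rows)

    def table2(self) -> pd.DataFrame:
        return pd.DataFrame(self.mvmr)

    def table3(self) -> pd.DataFrame:
        return pd.DataFrame(self.mediation)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_json(out / "report.json")
        self.table1().to_csv(out / "table1.tsv", sep="\t", index=False)
        self.table2().to_csv(out / "table2.tsv", sep="\t", index=False)
        self.table3().to_csv(out / "table3.tsv", sep="\t", index=False)


_REPORT_KEYS = {"provenance": dict, "univariable": dict, "mvmr": list, "mediation": list}
_DIRECTION_KEYS = ("stage_log", "estimates", "heterogeneity", "strength",
                   "presso", "leave_one_out", "verdict")


def validate_report(report: dict) -> None:
    """Schema check for a (possibly JSON-round-tripped) study report dict."""
    for key, typ in _REPORT_KEYS.items():
        if key not in report:
            raise FormatError(f"report missing key: {key}")
        if not isinstance(report[key], typ):
            raise FormatError(f"report key {key!r} has wrong type")
    for prov_key in ("seed", "version", "config"):
        if prov_key not in report["provenance"]:
            raise FormatError(f"report provenance missing: {prov_key}")
    for outcome, directions in report["univariable"].items():
        for direction, res in directions.items():
            if res.get("error"):
                continue
            for key in _DIRECTION_KEYS:
                if key not in res:
                    raise FormatError(
                        f"direction {outcome}/{direction} missing {key!r}")
            v = res["verdict"]
            expected = bool(v["pval_pass"] and v["direction_pass"] and v["pleiotropy_pass"])
            if bool(v["significant"]) != expected:
                raise FormatError(
                    f"verdict for {outcome}/{direction} not derivable from its criteria")


def load_manifest(source) -> dict:
    """Read a study manifest (YAML mapping) and check mandatory entries."""
    if isinstance(source, dict):
        manifest = dict(source)
    else:
        with open(source) as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ConfigurationError("manifest must be a mapping")
    for key in ("exposure", "outcomes", "seed"):
        if key not in manifest:
            raise ConfigurationError(f"manifest missing entry: {key}")
    if not manifest["outcomes"]:
        raise ConfigurationError("manifest lists no outcomes")
    return manifest


def _load_table(entry) -> pd.DataFrame:
    """A manifest entry is {'name': ..., 'file': path} or {'name': ..., 'table': DataFrame}."""
    if "table" in entry:
        return entry["table"]
    if "file" not in entry:
        raise ConfigurationError(f"manifest entry lacks 'file' or 'table': {entry}")
    table, _ = read_summary_table(entry["file"])
    return table


def run_full_study(manifest) -> StudyReport:
    """Execute the whole design described by a manifest.

    The manifest maps: ``exposure`` (name/file), ``outcomes`` (list of
    name/file), optional ``covariates`` (list of name/file; each is used
    both as an MVMR adjustment, one at a time, and as a candidate
    mediator), optional ``ld_matrix`` (TSV, square, header = snp ids),
    ``seed``, and any :class:`AnalysisConfig` field under ``config``.
    MVMR and mediation are run for outcomes whose forward univariable
    verdict is significant, mirroring a screen-then-explain design.
    """
    manifest = load_manifest(manifest)
    cfg_kwargs = dict(manifest.get("config") or {})
    config = AnalysisConfig(seed=int(manifest["seed"]), **cfg_kwargs)
    n_outcomes = len(manifest["outcomes"])
    if config.n_outcomes != n_outcomes:
        config = AnalysisConfig(**{**asdict(config), "n_outcomes": n_outcomes})

    exposure_name = manifest["exposure"].get("name", "exposure")
    exposure = _load_table(manifest["exposure"])
    ld_matrix = None
    if manifest.get("ld_matrix") is not None:
        entry = manifest["ld_matrix"]
        if isinstance(entry, (str, Path)):
            ld_matrix = pd.read_csv(entry, sep="\t", index_col=0)
        else:
            ld_matrix = entry

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "exposure": exposure_name,
        "outcomes": [o.get("name", f"outcome{i}") for i, o in enumerate(manifest["outcomes"])],
        "covariates": [c.get("name", f"cov{i}") for i, c in enumerate(manifest.get("covariates") or [])],
        "inputs": {
            k: str(v.get("file", "<in-memory>"))
            for k, v in {"exposure": manifest["exposure"]}.items()
        },
        "bonferroni_denominator": n_outcomes,
    }
    report = StudyReport(provenance=provenance)

    significant_outcomes = []
    for i, outcome_entry in enumerate(manifest["outcomes"]):
        outcome_name = outcome_entry.get("name", f"outcome{i}")
        outcome = _load_table(outcome_entry)
        directions = {}
        for direction, (exp_t, out_t) in {
            "forward": (exposure, outcome),
            "reverse": (outcome, exposure),
        }.items():
            label = (f"{exposure_name}->{outcome_name}" if direction == "forward"
                     else f"{outcome_name}->{exposure_name}")
            try:
                directions[direction] = run_univariable(
                    exp_t, out_t, ld_matrix, config, name=label).to_dict()
            except InstrumentSelectionError as err:
                directions[direction] = DirectionResult(
                    name=label, error=str(err)).to_dict()
        report.univariable[outcome_name] = directions
        fwd = directions["forward"]
        if not fwd.get("error") and fwd["verdict"]["significant"]:
            significant_outcomes.append((outcome_name, outcome))

    covariates = manifest.get("covariates") or []
    for outcome_name, outcome in significant_outcomes:
        for entry in covariates:
            cov_name = entry.get("name", "covariate")
            cov = _load_table(entry)
            try:
                ds = build_mvmr_dataset(
                    {exposure_name: exposure, cov_name: cov}, outcome,
                    p_threshold=config.p_threshold, ld_matrix=ld_matrix,
                    r2_threshold=config.r2_threshold, window_kb=config.window_kb,
                    palindrome_policy=config.palindrome_policy,
                    eaf_threshold=config.eaf_threshold)
                estimates, diag = mvmr_ivw(ds, level=config.level)
                direct = estimates[0]
                report.mvmr.append({
                    "outcome": outcome_name, "adjustment": cov_name,
                    "n_snp": ds.n_snps, "beta": direct.beta, "se": direct.se,
                    "or": direct.or_ci.odds_ratio,
                    "or_ci_low": direct.or_ci.ci_low,
                    "or_ci_high": direct.or_ci.ci_high, "pval": direct.pval,
                    "overdispersion_scale": diag["overdispersion_scale"],
                })
            except Exception as err:  # surfaced per covariate, not fatal
                report.mvmr.append({"outcome": outcome_name, "adjustment": cov_name,
                                    "error": f"{type(err).__name__}: {err}"})
            try:
                med = run_mediation(
                    exposure, cov, outcome, p_threshold=config.p_threshold,
                    beta2_method=config.beta2_method, ld_matrix=ld_matrix,
                    palindrome_policy=config.palindrome_policy,
                    eaf_threshold=config.eaf_threshold, level=config.level)
                report.mediation.append({
                    "outcome": outcome_name, "mediator": cov_name,
                    "beta1": med.beta1, "beta2": med.beta2,
                    "indirect": med.indirect, "indirect_se": med.indirect_se,
                    "indirect_pval": med.indirect_pval,
                    "proportion_pct": med.proportion * 100.0,
                    "proportion_ci_low_pct": med.proportion_ci[0] * 100.0,
                    "proportion_ci_high_pct": med.proportion_ci[1] * 100.0,
                    "pval": med.proportion_pval,
                })
            except Exception as err:
                report.mediation.append({"outcome": outcome_name, "mediator": cov_name,
                                         "error": f"{type(err).__name__}: {err}"})
    validate_report(json.loads(report.to_json()))
    return report
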