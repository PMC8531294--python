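"""End-to-end study orchestration.

Two studies tie the stages together:

* the tethering study runs extract -> thresholds -> density -> mask ->
  classify -> summarize per substrate (soft and stiff substrates are never
  pooled), writing significant-event tables, density grids, masks and the
  per-substrate tether summary;
* the stiffness study fits the Hertz model to every approach curve in a
  directory, grouped by gel, and writes per-curve fits plus the pooled
  modulus summary.

Every output table carries a provenance header with the configuration hash
and seed; re-running a study with the same configuration and inputs
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sbio
from .elasticity import NoContactError, fit_hertz, summarize_modulus
from .forcecurve import baseline_correct
from .signature import (
    cumulative_log2fc,
    direction_fractions,
    erk_concordance,
    permutation_systematic,
    validate_expression_table,
)
from .tethering import EventSet, analyze_tether_condition

__all__ = [
    "RunConfig",
    "run_tethering_study",
    "run_stiffness_study",
    "run_signature_study",
]

DEFAULT_PARAMS = {
    "ratio": 2.0,
    "kernel_size": 3,
    "n_bins": 30,
    "min_force_pN": 20.0,
    "nu": 0.5,
    "max_indentation_nm": None,
    "padj_threshold": 0.05,
    "min_abs": 0.2,
    "n_permutations": 999,
}

STUDIES = ("tethering", "stiffness", "signature", "simulate")


@dataclass
class RunConfig:
    """One study run: inputs, output directory, stage parameters, seed."""

    study: str
    inputs: dict = field(default_factory=dict)
    output_dir: str = "out"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r}; expected one of {STUDIES}")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        self.params = merged

    def validate_paths(self) -> None:
        for name, path in _walk_paths(self.inputs):
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name!r}: no such path: {path}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def provenance(self, **extra) -> dict:
        prov = {"config_hash": self.config_hash, "seed": self.seed, "study": self.study}
        prov.update(extra)
        return prov


def _walk_paths(inputs, prefix=""):
    for key, value in inputs.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            yield from _walk_paths(value, prefix=f"{name}.")
        else:
            yield name, value


def _prepare_output(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    return out


def _pool_events(sets: list[EventSet], probe: str, substrate: str) -> EventSet:
    events = tuple(ev for es in sets for ev in es.events)
    return EventSet(
        events=events,
        sample_id="pooled",
        probe=probe,
        substrate=substrate,
        n_curves_total=sum(es.n_curves_total for es in sets),
    )


def run_tethering_study(config: RunConfig) -> dict:
    """Classify significant tether ruptures per substrate and summarise.

    ``config.inputs`` maps substrate name to ``{"sample": <event TSV>,
    "control": <event TSV>}``.  Returns ``{substrate: TetherSummary}`` and
    writes grids, masks, significant events and summaries under
    ``config.output_dir``.
    """
    config.validate_paths()
    out = _prepare_output(config)
    p = config.params
    summaries = {}
    for substrate, paths in config.inputs.items():
        if "sample" not in paths or "control" not in paths:
            raise ValueError(f"substrate {substrate!r} needs 'sample' and 'control' paths")
        try:
            sample_sets = sbio.read_event_table(paths["sample"])
            control_sets = sbio.read_event_table(paths["control"])
            control = _pool_events(control_sets, probe="anti_IgG", substrate=substrate)
            result = analyze_tether_condition(
                sample_sets,
                control,
                ratio=p["ratio"],
                kernel_size=p["kernel_size"],
                n_bins=p["n_bins"],
            )
        except Exception as exc:
            raise RuntimeError(f"tethering stage failed for substrate {substrate!r}: {exc}") from exc
        sample_grid = result.sample_grid
        control_grid = result.control_grid
        mask = result.mask
        significant_sets = result.significant_sets
        summary = result.summary
        summaries[substrate] = summary

        prov = config.provenance(substrate=substrate, **{k: p[k] for k in ("ratio", "kernel_size", "n_bins")})
        sbio.write_event_table(significant_sets, out / f"{substrate}.significant_events.tsv", prov)
        sbio.write_grid(sample_grid, out / f"{substrate}.sample_density.tsv", prov)
        sbio.write_grid(control_grid, out / f"{substrate}.control_density.tsv", prov)
        sbio.write_mask(mask, sample_grid, out / f"{substrate}.mask.tsv", prov)
        rows = [
            {
                "sample_id": sid,
                "mean_log10_force": summary.per_sample_mean_log10_force.get(sid, np.nan),
                "n_significant": summary.n_significant_events_per_sample[sid],
            }
            for sid in sorted(summary.n_significant_events_per_sample)
        ]
        summary_df = pd.DataFrame(rows, columns=["sample_id", "mean_log10_force", "n_significant"])
        prov["overall_mean_log10_force"] = (
            "no_significant_binding"
            if summary.no_significant_binding
            else repr(summary.overall_mean_log10_force)
        )
        prov["sem_log10_force"] = (
            "" if summary.sem_log10_force is None else repr(summary.sem_log10_force)
        )
        sbio.write_tsv(summary_df, out / f"{substrate}.tether_summary.tsv", prov)
    return summaries


def run_stiffness_study(config: RunConfig) -> dict:
    """Fit the Hertz model to every curve file and summarise per group.

    ``config.inputs['curves']`` is a directory of force-curve files; curves
    are grouped by their ``sample_id`` (the gel id).  Writes per-curve fits,
    the pooled summary, and a log of rejected curves with reasons.
    """
    config.validate_paths()
    out = _prepare_output(config)
    p = config.params
    curve_dir = Path(config.inputs["curves"])
    fit_rows = []
    rejected = []
    fits_by_gel: dict[str, list] = {}
    for path in sorted(curve_dir.glob("*.tsv")):
        try:
            curve = sbio.read_force_curve(path)
            approach, _ = baseline_correct(curve.approach)
            fit = fit_hertz(
                approach,
                bead_radius_um=curve.bead_radius_um,
                spring_constant=curve.spring_constant,
                poisson_ratio=p["nu"],
                max_indentation_nm=p["max_indentation_nm"],
            )
        except (ValueError, KeyError, NoContactError, TypeError) as exc:
            rejected.append({"file": path.name, "reason": str(exc)})
            continue
        fits_by_gel.setdefault(curve.sample_id, []).append(fit)
        fit_rows.append(
            {
                "curve_id": curve.curve_id,
                "gel_id": curve.sample_id,
                "youngs_modulus_Pa": fit.youngs_modulus_Pa,
                "contact_point_nm": fit.contact_point_nm,
                "residual_rms_pN": fit.residual_rms_pN,
                "n_points_in_contact": fit.n_points_in_contact,
            }
        )
    prov = config.provenance(nu=p["nu"])
    sbio.write_tsv(
        pd.DataFrame(
            fit_rows,
            columns=[
                "curve_id",
                "gel_id",
                "youngs_modulus_Pa",
                "contact_point_nm",
                "residual_rms_pN",
                "n_points_in_contact",
            ],
        ),
        out / "hertz_fits.tsv",
        prov,
    )
    sbio.write_tsv(
        pd.DataFrame(rejected, columns=["file", "reason"]), out / "rejected_curves.tsv", prov
    )
    if not fits_by_gel:
        raise RuntimeError("stiffness study: no curve could be fitted")
    summary = summarize_modulus(fits_by_gel)
    per_gel = pd.DataFrame(
        [{"gel_id": gel, "mean_E_Pa": m} for gel, m in sorted(summary.per_gel_mean_Pa.items())],
        columns=["gel_id", "mean_E_Pa"],
    )
    prov.update(
        mean_E_Pa=repr(summary.mean_E_Pa),
        sd_E_Pa=repr(summary.sd_E_Pa),
        n_indentations=summary.n_indentations,
        n_gels=summary.n_gels,
    )
    sbio.write_tsv(per_gel, out / "modulus_summary.tsv", prov)
    return {"summary": summary, "n_rejected": len(rejected)}


def run_signature_study(config: RunConfig) -> dict:
    """Signature statistics over an expression table.

    ``config.inputs['expression']`` is the per-gene TSV.  Optional
    ``config.inputs['gene_set']`` (one gene id per line) triggers the
    permutation test.  Statistics run per condition label.
    """
    config.validate_paths()
    out = _prepare_output(config)
    p = config.params
    table = sbio.read_expression_table(config.inputs["expression"])
    validate_expression_table(table)
    results: dict = {"cumulative": [], "directions": [], "erk": None, "permutation": None}
    conditions = table["condition"].unique() if "condition" in table.columns else [""]
    cum_rows = []
    dir_rows = []
    for condition in conditions:
        sub = table[table["condition"] == condition] if condition != "" else table
        for cluster in sub["cluster"].unique():
            if cluster == "none":
                continue
            cum = cumulative_log2fc(sub, cluster, min_abs=p["min_abs"], condition=str(condition))
            frac = direction_fractions(sub, cluster, padj_threshold=p["padj_threshold"])
            results["cumulative"].append(cum)
            results["directions"].append(frac)
            cum_rows.append(
                {
                    "condition": condition,
                    "cluster": cluster,
                    "included_genes": cum.included_genes,
                    "endpoint": cum.endpoint,
                }
            )
            dir_rows.append(
                {
                    "condition": condition,
                    "cluster": cluster,
                    "pct_up": np.nan if frac.pct_up is None else frac.pct_up,
                    "pct_down": np.nan if frac.pct_down is None else frac.pct_down,
                    "n_significant": frac.n_significant,
                }
            )
    prov = config.provenance(min_abs=p["min_abs"], padj_threshold=p["padj_threshold"])
    sbio.write_tsv(
        pd.DataFrame(cum_rows, columns=["condition", "cluster", "included_genes", "endpoint"]),
        out / "cumulative_log2fc.tsv",
        prov,
    )
    sbio.write_tsv(
        pd.DataFrame(
            dir_rows, columns=["condition", "cluster", "pct_up", "pct_down", "n_significant"]
        ),
        out / "direction_fractions.tsv",
        prov,
    )
    clusters_present = set(table["cluster"])
    if {"erk_activated", "erk_suppressed"} <= clusters_present:
        results["erk"] = erk_concordance(table, padj_threshold=p["padj_threshold"])
    if "gene_set" in config.inputs:
        gene_set = [
            line.strip()
            for line in Path(config.inputs["gene_set"]).read_text().splitlines()
            if line.strip()
        ]
        results["permutation"] = permutation_systematic(
            table, gene_set, n_permutations=p["n_permutations"], seed=config.seed
        )
        perm = results["permutation"]
        sbio.write_tsv(
            pd.DataFrame(
                [
                    {
                        "observed_statistic": perm.observed_statistic,
                        "p_value": perm.p_value,
                        "n_permutations": perm.n_permutations,
                    }
                ]
            ),
            out / "permutation.tsv",
            prov,
        )
    return results
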