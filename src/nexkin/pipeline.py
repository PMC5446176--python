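"""End-to-end simulate -> fit -> report runs.

A :class:`RunConfig` describes a full experiment battery: association and
chase assays for both nucleotides, EF-Ts titrations on both branches,
the five GTPase conditions and the protection decays, each repeated at
every configured tetracycline level.  :func:`run_pipeline` materializes
the synthetic records, runs the staged analysis, and reports a rate table
in the conventional scaled units together with per-constant comparison
verdicts across tetracycline levels.  Everything is deterministic given
the config (all randomness is seeded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analyze import (
    RateEstimate,
    association_analysis,
    chase_analysis,
    compare_conditions,
    exchange_relaxation_correction,
    group_fits,
    gtpase_rate_from_replicates,
    protection_halflife,
    ts_titration_analysis,
)
from .designs import (
    AssociationDesign,
    ChaseDesign,
    GtpaseDesign,
    ProtectionDesign,
    TsTitrationDesign,
)
from .fitting import fit_single_exponential
from .generate import (
    generate_association_set,
    generate_chase_set,
    generate_gtpase_timecourse,
    generate_protection_decay,
    generate_ts_titration_set,
)
from .records import write_timecourse
from .truth import GTPASE_CONDITIONS, default_truth

log = logging.getLogger("nexkin.pipeline")

__all__ = ["RunConfig", "run_pipeline", "REPORT_SCALES"]

#: reporting convention per constant: (scale factor, printed unit)
REPORT_SCALES = {
    "k1": (1e6, "x10^6 M^-1 s^-1"),
    "k5": (1e5, "x10^5 M^-1 s^-1"),
    "k1r": (1e-3, "x10^-3 s^-1"),
    "k5r": (1e-2, "x10^-2 s^-1"),
    "combined_gdp": (1e6, "x10^6 M^-1 s^-1"),
    "combined_gtp": (1e6, "x10^6 M^-1 s^-1"),
    "kGTPase_intrinsic": (1e-4, "x10^-4 uM/s"),
    "kGTPase_EF-Ts_0.02uM": (1e-4, "x10^-4 uM/s"),
    "kGTPase_EF-Ts_0.2uM": (1e-4, "x10^-4 uM/s"),
    "kGTPase_70S": (1e-3, "x10^-3 uM/s"),
    "kGTPase_50S": (1e-3, "x10^-3 uM/s"),
    "t_half_free": (1.0, "min"),
    "t_half_protected": (1.0, "min"),
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``effect_hook`` maps a constant name to a multiplicative factor applied
    to the generating truth at every non-zero tetracycline level — the
    counterfactual in which the drug does perturb that step.
    ``protection_tet_levels`` lists the tetracycline levels of the
    protected decay series (the unprotected series is run at 0 uM only).
    """

    seed: int = 0
    tet_levels: tuple = (0.0, 100.0)
    protection_tet_levels: tuple = (0.0, 3.0, 30.0, 100.0)
    outdir: str | None = None
    write_records: bool = True
    alpha: float = 0.05
    effect_hook: dict = field(default_factory=dict)
    association_replicates: int = 11
    chase_replicates: int = 10
    ts_replicates: int = 12
    gtpase_replicates: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = raw.keys() - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tet_levels", "protection_tet_levels"):
            if key in raw:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["tet_levels"] = list(self.tet_levels)
        data["protection_tet_levels"] = list(self.protection_tet_levels)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _truth_for(config: RunConfig, tet: float):
    truth = default_truth(tet)
    if config.effect_hook and tet > 0:
        truth = truth.with_effect(**{
            k: float(v) for k, v in config.effect_hook.items()
        })
    return truth


def _seed_for(config: RunConfig, *labels) -> np.random.SeedSequence:
    # stable across processes (unlike builtin hash)
    key = tuple(zlib.crc32(str(l).encode()) for l in labels)
    return np.random.SeedSequence(entropy=config.seed, spawn_key=key)


def _maybe_write(records, outdir, subdir, config):
    if not (config.write_records and outdir):
        return
    base = Path(outdir) / "records" / subdir
    for i, rec in enumerate(records):
        write_timecourse(rec, base / f"trace_{i:04d}.csv")


def run_pipeline(config: RunConfig):
    """Run the full battery and return ``(rate_table, comparisons)``.

    ``rate_table`` has one row per (constant, condition) with values in the
    conventional scaled units; ``comparisons`` holds the per-constant
    zero-versus-nonzero tetracycline verdicts.  When ``config.outdir`` is
    set, intermediate records, both tables and a provenance log are written
    there.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    estimates: dict[tuple, RateEstimate] = {}
    provenance = {"seed": config.seed, "assays": []}

    for tet in config.tet_levels:
        truth = _truth_for(config, tet)
        tag = f"tet{tet:g}"

        for nuc in ("GDP", "GTP"):
            # association titration
            concs = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0) if nuc == "GDP" \
                else (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
            a_design = AssociationDesign(
                nucleotide=nuc, ligand_concs_uM=concs,
                replicates=config.association_replicates,
            )
            seed = _seed_for(config, "association", nuc, tet)
            recs = generate_association_set(a_design, truth, seed)
            _maybe_write(recs, outdir, f"{tag}/association_{nuc}", config)
            slope, _ = association_analysis(
                group_fits(recs, "ligand_conc_uM"), nuc,
                (("tet_uM", tet),), tu_conc_uM=a_design.tu_conc_uM,
            )
            estimates[(slope.name, tet)] = slope
            provenance["assays"].append(
                {"family": "association", "nucleotide": nuc, "tet_uM": tet,
                 "n_traces": len(recs)}
            )

            # dissociation chase
            c_design = ChaseDesign(
                nucleotide=nuc, replicates=config.chase_replicates
            )
            seed = _seed_for(config, "chase", nuc, tet)
            recs = generate_chase_set(c_design, truth, seed)
            _maybe_write(recs, outdir, f"{tag}/chase_{nuc}", config)
            est = chase_analysis(
                [fit_single_exponential(r) for r in recs], nuc,
                (("tet_uM", tet),),
                rebinding_correction=exchange_relaxation_correction(
                    recs[0].meta
                ),
            )
            estimates[(est.name, tet)] = est
            provenance["assays"].append(
                {"family": "chase", "nucleotide": nuc, "tet_uM": tet,
                 "n_traces": len(recs)}
            )

            # EF-Ts titration
            t_design = TsTitrationDesign(
                nucleotide=nuc, replicates=config.ts_replicates
            )
            seed = _seed_for(config, "ts_titration", nuc, tet)
            recs = generate_ts_titration_set(t_design, truth, seed)
            _maybe_write(recs, outdir, f"{tag}/ts_titration_{nuc}", config)
            est = ts_titration_analysis(
                group_fits(recs, "ts_conc_uM"), nuc, (("tet_uM", tet),)
            )
            estimates[(est.name, tet)] = est
            provenance["assays"].append(
                {"family": "ts_titration", "nucleotide": nuc, "tet_uM": tet,
                 "n_traces": len(recs)}
            )

        # GTPase conditions
        for condition in GTPASE_CONDITIONS:
            g_design = GtpaseDesign(
                condition=condition, replicates=config.gtpase_replicates
            )
            seed = _seed_for(config, "gtpase", condition, tet)
            suite = generate_gtpase_timecourse(g_design, truth, seed)
            _maybe_write(
                suite.reaction + suite.background, outdir,
                f"{tag}/gtpase_{condition}", config,
            )
            est = gtpase_rate_from_replicates(suite, (("tet_uM", tet),))
            estimates[(est.name, tet)] = est
            provenance["assays"].append(
                {"family": "gtpase", "condition": condition, "tet_uM": tet,
                 "n_replicates": config.gtpase_replicates}
            )

    # protection decays: unprotected at 0 uM, protected at its own levels
    p_free = ProtectionDesign(tu_conc_uM=0.0)
    rec = generate_protection_decay(p_free, default_truth(0.0),
                                    _seed_for(config, "protection", "free", 0.0))
    _maybe_write([rec], outdir, "tet0/protection_free", config)
    est = protection_halflife(rec, (("tet_uM", 0.0),))
    estimates[(est.name, 0.0)] = est
    for tet in config.protection_tet_levels:
        truth = _truth_for(config, tet)
        p_design = ProtectionDesign()
        seed = _seed_for(config, "protection", "protected", tet)
        rec = generate_protection_decay(p_design, truth, seed)
        _maybe_write([rec], outdir, f"tet{tet:g}/protection", config)
        est = protection_halflife(rec, (("tet_uM", tet),))
        estimates[(est.name, tet)] = est
        provenance["assays"].append(
            {"family": "protection", "tet_uM": tet}
        )

    rate_table = _build_rate_table(estimates)
    comparisons = _build_comparisons(estimates, config)

    if outdir:
        rate_table.to_csv(outdir / "rate_table.csv", index=False,
                          float_format="%.10g")
        rate_table.to_json(outdir / "rate_table.json", orient="records",
                           indent=1)
        comparisons.to_csv(outdir / "comparisons.csv", index=False,
                           float_format="%.10g")
        with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
        log.info("pipeline artifacts written to %s", outdir)
    return rate_table, comparisons


def _build_rate_table(estimates: dict) -> pd.DataFrame:
    rows = []
    for (name, tet), est in sorted(estimates.items()):
        scale, unit = REPORT_SCALES.get(name, (1.0, est.units))
        rows.append({
            "constant": name,
            "tet_uM": tet,
            "value": est.value / scale,
            "se": est.se / scale if np.isfinite(est.se) else np.nan,
            "units": unit,
            "n": est.n,
            "flags": "; ".join(est.flags),
        })
    return pd.DataFrame(rows)


def _build_comparisons(estimates: dict, config: RunConfig) -> pd.DataFrame:
    rows = []
    names = sorted({name for name, _ in estimates})
    for name in names:
        base = estimates.get((name, 0.0))
        if base is None or not np.isfinite(base.se):
            continue
        for (n2, tet), est in sorted(estimates.items()):
            if n2 != name or tet == 0.0 or not np.isfinite(est.se):
                continue
            cmp = compare_conditions(base, est, config.alpha)
            scale, unit = REPORT_SCALES.get(name, (1.0, base.units))
            rows.append({
                "constant": name,
                "tet_uM": tet,
                "value_0": base.value / scale,
                "value_tet": est.value / scale,
                "z": cmp.z,
                "p_value": cmp.p_value,
                "verdict": cmp.verdict,
            })
    return pd.DataFrame(rows)
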