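"""End-to-end pipeline: simulate cohorts, run every analysis stage, and
compute the group statistics, writing tidy CSV outputs and a run log.

The default configuration reproduces the study conditions: per-side cohort
sizes (15/16 patched neurons, 141/109 and 115/69 imaged ROIs, two stains of
sectioned DRG), planted effect sizes equal to the reported proportions, and
the printed summary inputs (2x2 counts, mean/SD/n) for the summary-statistic
comparisons.  Reruns with the same config and seed are bit-identical
(timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from . import ephys_cc as cc
from . import ephys_vc as vc
from . import ihc as ihcmod
from . import synth
from .traces import CurrentStepProtocol
from .stats import (
    ContingencyTable2x2,
    GroupSummary,
    TestResult,
    chi_square_2x2,
    unpaired_t_samples,
    unpaired_t_summary,
)

log = logging.getLogger("drgsens")

CTRL, OD = "Ctrl", "OD"


class PipelineError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# configuration blocks (defaults are the study conditions)

@dataclass
class EphysConfig:
    n_per_side: dict = field(default_factory=lambda: {CTRL: 15, OD: 16})
    n_animals: int = 3
    spontaneous_fraction: dict = field(default_factory=lambda: {CTRL: 0.2033, OD: 0.50})
    multiple_firing_fraction: dict = field(default_factory=lambda: {CTRL: 0.2833, OD: 0.78})
    capsaicin_responder_fraction: dict = field(
        default_factory=lambda: {CTRL: 6 / 15, OD: 12 / 16})
    abmeatp_responder_fraction: dict = field(
        default_factory=lambda: {CTRL: 3 / 15, OD: 4 / 16})
    spontaneous_rate_hz: float = 0.5
    spontaneous_window_s: float = 30.0
    noise_sd_mV: float = 0.5
    # per-side spike-fall duration (mean, SD) controlling the planted HPD
    # difference (broader APs on the OD side), and the RMP spread
    hpd_fall_ms: dict = field(default_factory=lambda: {CTRL: (8.5, 4.0), OD: (13.5, 7.0)})
    rmp_sd_mV: float = 10.0


@dataclass
class VoltageClampConfig:
    n_per_side: int = 6
    noise_sd_pA: float = 20.0


@dataclass
class CalciumConfig:
    # per agonist, per side: (n ROIs, planted responder fraction)
    cohorts: dict = field(default_factory=lambda: {
        ca.CAPSAICIN: {CTRL: (141, 35 / 141), OD: (109, 48 / 109)},
        ca.ABMEATP: {CTRL: (115, 24 / 115), OD: (69, 23 / 69)},
    })
    amplitude_rel_kcl_mean: float = 0.4
    amplitude_rel_kcl_sd: float = 0.15
    noise_sd: float = 0.005
    kcl_select_k: float = 5.0


@dataclass
class IHCConfig:
    n_sections: int = 6
    neurons_per_section: int = 300
    positive_fraction: dict = field(default_factory=lambda: {
        "P2X3": {CTRL: 1459 / 4758, OD: 1631 / 5133},
        "CGRP": {CTRL: 1135 / 3524, OD: 1033 / 3413},
    })
    size_cutoffs: tuple = (600.0, 1000.0)


#: printed summary inputs: 2x2 responder counts and mean/SD/n summaries
PRINTED_COUNTS = {
    "capsaicin_ap": (6, 15, 12, 16),
    "abmeatp_ap": (3, 15, 4, 16),
    "capsaicin_ca": (35, 141, 48, 109),
    "abmeatp_ca": (24, 115, 23, 69),
    "p2x3_ihc": (1459, 4758, 1631, 5133),
    "cgrp_ihc": (1135, 3524, 1033, 3413),
}
PRINTED_SUMMARIES = {
    "spontaneous_pct": ((20.33, 4.5, 3), (50.0, 10.0, 3), 3),
    "multiple_firing_pct": ((28.33, 10.41, 3), (78.0, 19.05, 3), 2),
    "hpd_ms": ((3.13, 0.88, 15), (4.48, 2.15, 16), 2),
    "rmp_mV": ((-48.27, 13.39, 15), (-46.5, 9.63, 16), 2),
}
#: decimal places of each printed chi-square p-value
PRINTED_COUNT_DECIMALS = {
    "capsaicin_ap": 2, "abmeatp_ap": 2, "capsaicin_ca": 3,
    "abmeatp_ca": 2, "p2x3_ihc": 2, "cgrp_ihc": 2,
}


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple = ("printed_stats", "ephys_cc", "ephys_vc", "calcium", "ihc")
    ephys: EphysConfig = field(default_factory=EphysConfig)
    voltage_clamp: VoltageClampConfig = field(default_factory=VoltageClampConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    ihc: IHCConfig = field(default_factory=IHCConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        blocks = {
            "ephys": EphysConfig, "voltage_clamp": VoltageClampConfig,
            "calcium": CalciumConfig, "ihc": IHCConfig,
        }
        kwargs = {}
        for key, value in d.items():
            if key in blocks:
                kwargs[key] = blocks[key](**value)
            elif key == "stages":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _result_row(comparison: str, res: TestResult, **extra) -> dict:
    return {
        "comparison": comparison, "statistic": res.statistic, "df": res.df,
        "p_two_sided": res.p_two_sided, "p_printed": res.p_printed,
        "method": res.method, **extra,
    }


# --------------------------------------------------------------------------
# stages

def printed_stats() -> pd.DataFrame:
    """The summary-statistic comparisons computed from the printed inputs."""
    rows = []
    for name, (k1, n1, k2, n2) in PRINTED_COUNTS.items():
        res = chi_square_2x2(
            ContingencyTable2x2.from_proportions(k1, n1, k2, n2),
            p_decimals=PRINTED_COUNT_DECIMALS[name],
        )
        rows.append(_result_row(name, res, n=n1 + n2))
    for name, (g1, g2, dec) in PRINTED_SUMMARIES.items():
        res = unpaired_t_summary(GroupSummary(*g1), GroupSummary(*g2), p_decimals=dec)
        rows.append(_result_row(name, res, n=g1[2] + g2[2]))
    return pd.DataFrame(rows)


def _animal_week(i: int) -> int:
    return (2, 4, 6)[i % 3]


def run_ephys_cc(cfg: EphysConfig, seed_seq: np.random.SeedSequence):
    """Simulate both patched cohorts, extract features and classify."""
    rng = np.random.default_rng(seed_seq)
    protocol = CurrentStepProtocol()
    rows = []
    for side in (CTRL, OD):
        n = cfg.n_per_side[side]
        spont = synth.planted_labels(rng, n, cfg.spontaneous_fraction[side])
        multi = synth.planted_labels(rng, n, cfg.multiple_firing_fraction[side])
        caps = synth.planted_labels(rng, n, cfg.capsaicin_responder_fraction[side])
        atp = synth.planted_labels(rng, n, cfg.abmeatp_responder_fraction[side])
        for i in range(n):
            animal = i % cfg.n_animals
            rmp = float(np.clip(rng.normal(-48.3, cfg.rmp_sd_mV), -70.0, -35.0))
            fall_mean, fall_sd = cfg.hpd_fall_ms[side]
            template = synth.SpikeTemplate(
                fall_ms=float(np.clip(rng.normal(fall_mean, fall_sd), 2.0, 35.0)),
                peak_mV=rmp + 101.6)
            level_idx = int(rng.integers(0, 5))
            params = synth.EphysSimParams(
                rmp_mV=rmp,
                spike_template=template,
                spontaneous_rate_hz=cfg.spontaneous_rate_hz if spont[i] else 0.0,
                rheobase_pA=float(protocol.levels_pA[level_idx]),
                noise_sd_mV=cfg.noise_sd_mV,
                capacitance_pF=float(np.clip(rng.normal(75.0, 30.0), 15.0, 200.0)),
                evoked_spikes_per_step=4 if multi[i] else 1,
            )
            meta = {
                "neuron_id": f"{side}_n{i:02d}",
                "animal_id": f"S{animal + 1}",
                "side": side,
                "weeks_post_od": _animal_week(animal),
            }
            quiet, _ = synth.simulate_current_clamp(
                dataclasses.replace(params, spontaneous_rate_hz=0.0),
                duration_s=1.0, rng=rng, metadata=meta)
            rmp_meas = cc.measure_rmp(quiet[0], (0.0, 1.0))
            spont_trace, _ = synth.simulate_current_clamp(
                params, duration_s=cfg.spontaneous_window_s, rng=rng, metadata=meta)
            is_spont = cc.classify_spontaneous(spont_trace[0])
            sweeps, _ = synth.simulate_current_clamp(
                params, protocol=protocol, rng=rng, metadata=meta)
            rheo = cc.find_rheobase(sweeps)
            is_multi = cc.classify_multiple_firing(sweeps)
            feats = cc.APFeatures(float("nan"), float("nan"), float("nan"), float("nan"))
            if rheo.reached:
                feats = cc.extract_ap_features(
                    sweeps[rheo.sweep_index], rheo.first_spike, rmp_meas)
            base_c, ag_c = synth.simulate_agonist_pair(params, bool(caps[i]), rng=rng)
            caps_resp = cc.score_agonist_response(base_c, ag_c, ca.CAPSAICIN)
            base_a, ag_a = synth.simulate_agonist_pair(params, bool(atp[i]), rng=rng)
            atp_resp = cc.score_agonist_response(base_a, ag_a, ca.ABMEATP)
            rows.append({
                **meta,
                "rmp_mV": rmp_meas,
                "rheobase_pA": rheo.level_pA if rheo.reached else np.nan,
                "amplitude_mV": feats.amplitude_mV,
                "hpd_ms": feats.hpd_ms,
                "ahp_amplitude_mV": feats.ahp_amplitude_mV,
                "ahp_duration_ms": feats.ahp_duration_ms,
                "capacitance_pF": params.capacitance_pF,
                "diameter_um": float(np.clip(rng.normal(39.5, 8.0), 15.0, 70.0)),
                "spontaneous": is_spont,
                "multiple_firing": is_multi,
                "capsaicin_above_baseline": caps_resp.above_baseline,
                "capsaicin_delta_rate_hz": caps_resp.delta_spike_rate_hz,
                "abmeatp_above_baseline": atp_resp.above_baseline,
                "abmeatp_delta_rate_hz": atp_resp.delta_spike_rate_hz,
                "true_spontaneous": bool(spont[i]),
                "true_multiple_firing": bool(multi[i]),
                "true_capsaicin_responder": bool(caps[i]),
                "true_abmeatp_responder": bool(atp[i]),
            })
    features = pd.DataFrame(rows)

    results = []
    # per-animal percentages compared across animals by t-test
    for col, name in (("spontaneous", "spontaneous_pct"),
                      ("multiple_firing", "multiple_firing_pct")):
        per_animal = features.groupby(["side", "animal_id"])[col].mean() * 100.0
        res = unpaired_t_samples(
            per_animal[CTRL].to_numpy(), per_animal[OD].to_numpy(), p_decimals=2)
        results.append(_result_row(f"{name}_simulated", res, n=2 * cfg.n_animals))
    # pooled neuron counts compared by chi-square
    for col, name in (("capsaicin_above_baseline", "capsaicin_ap"),
                      ("abmeatp_above_baseline", "abmeatp_ap")):
        k1 = int(features.loc[features.side == CTRL, col].sum())
        k2 = int(features.loc[features.side == OD, col].sum())
        n1 = int((features.side == CTRL).sum())
        n2 = int((features.side == OD).sum())
        res = chi_square_2x2(ContingencyTable2x2.from_proportions(k1, n1, k2, n2))
        results.append(_result_row(f"{name}_simulated", res, n=n1 + n2))
    # per-neuron feature comparisons
    for col, name in (("hpd_ms", "hpd_ms"), ("rmp_mV", "rmp_mV")):
        x1 = features.loc[features.side == CTRL, col].dropna().to_numpy()
        x2 = features.loc[features.side == OD, col].dropna().to_numpy()
        res = unpaired_t_samples(x1, x2)
        results.append(_result_row(f"{name}_simulated", res, n=x1.size + x2.size))
    return features, pd.DataFrame(results)


def run_ephys_vc(cfg: VoltageClampConfig, seed_seq: np.random.SeedSequence):
    """Simulate voltage-clamp cells per side, compute I-V densities, fit
    Boltzmann curves per neuron, and compare groups per voltage."""
    rng = np.random.default_rng(seed_seq)
    iv_rows, fit_rows = [], []
    densities: dict[str, dict[str, dict[float, list[float]]]] = {
        "inward": {CTRL: {}, OD: {}}, "outward": {CTRL: {}, OD: {}},
    }
    for side in (CTRL, OD):
        for cell in range(cfg.n_per_side):
            params = synth.VCSimParams(
                inward=synth.BoltzmannComponent(
                    float(rng.normal(-2000.0, 200.0)), float(rng.normal(-20.0, 2.0)), 6.0),
                outward=synth.BoltzmannComponent(
                    float(rng.normal(4000.0, 400.0)), float(rng.normal(0.0, 2.0)), 12.0),
                leak_pA=float(rng.normal(0.0, 30.0)),
                noise_sd_pA=cfg.noise_sd_pA,
                capacitance_pF=float(np.clip(rng.normal(75.0, 25.0), 20.0, 200.0)),
            )
            sweeps, _ = synth.simulate_voltage_clamp(params, rng=rng)
            points = [
                vc.compute_current_density(vc.subtract_baseline(sw), params.capacitance_pF)
                for sw in sweeps
            ]
            neuron_id = f"{side}_vc{cell:02d}"
            for p in points:
                iv_rows.append({
                    "neuron_id": neuron_id, "side": side, "step_mV": p.step_mV,
                    "inward_pA_per_pF": p.inward_density_pA_per_pF,
                    "outward_pA_per_pF": p.outward_density_pA_per_pF,
                })
                densities["inward"][side].setdefault(p.step_mV, []).append(
                    p.inward_density_pA_per_pF)
                densities["outward"][side].setdefault(p.step_mV, []).append(
                    p.outward_density_pA_per_pF)
            for branch in ("inward", "outward"):
                fit = vc.fit_boltzmann(points, branch=branch, components=1)
                row = {"neuron_id": neuron_id, "side": side, "branch": branch,
                       "converged": fit.converged,
                       "rss": fit.residual_sum_of_squares}
                if fit.converged:
                    row.update({f"{k}": v for k, v in fit.components[0].items()})
                fit_rows.append(row)
    comparisons = pd.concat([
        vc.compare_iv(densities[branch][CTRL], densities[branch][OD], branch_label=branch)
        for branch in ("inward", "outward")
    ], ignore_index=True)
    return pd.DataFrame(iv_rows), pd.DataFrame(fit_rows), comparisons


def run_calcium(cfg: CalciumConfig, seed_seq: np.random.SeedSequence):
    """Simulate one dish per agonist and side, run the ROI pipeline, and
    compare responder proportions."""
    rng = np.random.default_rng(seed_seq)
    amp = synth.NormalSpec(cfg.amplitude_rel_kcl_mean, cfg.amplitude_rel_kcl_sd)
    all_responses = []
    for agonist, sides in cfg.cohorts.items():
        protocol = ca.PerfusionProtocol.standard(agonists=(agonist,))
        for side, (n, fraction) in sides.items():
            params = synth.CalciumSimParams(
                n_rois=n,
                responder_fraction={agonist: fraction},
                amplitude_rel_kcl=amp,
                noise_sd=cfg.noise_sd,
                protocol=protocol,
            )
            rois, _truth = synth.simulate_calcium(
                rng=rng, params=params,
                metadata={"dish_id": f"{side}_{agonist}", "side": side},
            )
            background = next(r for r in rois if r.is_background)
            cells = [r for r in rois if not r.is_background]
            responses = ca.analyze_dish(
                cells, background, protocol, kcl_select_k=cfg.kcl_select_k)
            all_responses.append(responses)
    responses = pd.concat(all_responses, ignore_index=True)
    proportions = ca.summarize_proportions(responses)

    results = []
    for agonist in cfg.cohorts:
        sub = proportions[proportions.agonist == agonist].set_index("side")
        res = chi_square_2x2(ContingencyTable2x2.from_proportions(
            int(sub.loc[CTRL, "responders"]), int(sub.loc[CTRL, "total"]),
            int(sub.loc[OD, "responders"]), int(sub.loc[OD, "total"]),
        ))
        short = "capsaicin" if agonist == ca.CAPSAICIN else "abmeatp"
        results.append(_result_row(
            f"{short}_ca_simulated", res,
            n=int(sub["total"].sum()),
        ))
    return responses, proportions, pd.DataFrame(results)


def run_ihc(cfg: IHCConfig, seed_seq: np.random.SeedSequence):
    """Simulate stained sections per stain and side, score by the
    distribution-of-minima rule, and compare positive proportions."""
    rng = np.random.default_rng(seed_seq)
    records = []
    for stain, sides in cfg.positive_fraction.items():
        for side, fraction in sides.items():
            params = synth.IHCSimParams(
                n_sections=cfg.n_sections,
                neurons_per_section=cfg.neurons_per_section,
                positive_fraction=fraction,
            )
            df, _labels = synth.simulate_ihc(
                params, rng=rng, animal_id="A1", side=side, stain=stain)
            records.append(df)
    records = pd.concat(records, ignore_index=True)
    scored = ihcmod.score_dataset(records, scope=("animal_id", "stain", "side"))
    cutoffs = ihcmod.SizeCutoffs(*cfg.size_cutoffs)
    scored["size_category"] = ihcmod.categorize_size(scored["area_um2"], cutoffs)
    summary = ihcmod.summarize_positivity(scored)

    results = []
    for stain in cfg.positive_fraction:
        sub = summary[summary.stain == stain].set_index("side")
        res = chi_square_2x2(ContingencyTable2x2.from_proportions(
            int(sub.loc[CTRL, "positives"]), int(sub.loc[CTRL, "total"]),
            int(sub.loc[OD, "positives"]), int(sub.loc[OD, "total"]),
        ))
        results.append(_result_row(
            f"{stain.lower()}_ihc_simulated", res, n=int(sub["total"].sum())))
    return scored, summary, pd.DataFrame(results)


# --------------------------------------------------------------------------
# orchestration

def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the configured stages, write outputs under ``outdir``, and return
    the result tables.  Identical config and seed give identical outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(
        ("ephys_cc", "ephys_vc", "calcium", "ihc"), root_seq.spawn(4)))

    out: dict = {}
    counts: dict = {}
    all_results = []
    for stage in config.stages:
        log.info("stage %s: starting", stage)
        try:
            if stage == "printed_stats":
                res = printed_stats()
                out["printed_stats"] = res
                res.to_csv(outdir / "printed_stats.csv", index=False)
                counts[stage] = {"comparisons": len(res)}
                all_results.append(res)
            elif stage == "ephys_cc":
                features, res = run_ephys_cc(config.ephys, stage_seeds[stage])
                out["ephys_features"] = features
                out["ephys_results"] = res
                features.to_csv(outdir / "ephys_features.csv", index=False)
                counts[stage] = {"neurons": len(features)}
                all_results.append(res)
            elif stage == "ephys_vc":
                iv, fits, res = run_ephys_vc(config.voltage_clamp, stage_seeds[stage])
                out["iv_points"] = iv
                out["boltzmann_fits"] = fits
                out["iv_comparisons"] = res
                iv.to_csv(outdir / "iv_points.csv", index=False)
                fits.to_csv(outdir / "boltzmann_fits.csv", index=False)
                res.to_csv(outdir / "iv_comparisons.csv", index=False)
                counts[stage] = {"iv_points": len(iv), "fits": len(fits)}
            elif stage == "calcium":
                responses, proportions, res = run_calcium(config.calcium, stage_seeds[stage])
                out["calcium_responses"] = responses
                out["calcium_proportions"] = proportions
                responses.to_csv(outdir / "calcium_responses.csv", index=False)
                proportions.to_csv(outdir / "calcium_proportions.csv", index=False)
                counts[stage] = {"responses": len(responses)}
                all_results.append(res)
            elif stage == "ihc":
                scored, summary, res = run_ihc(config.ihc, stage_seeds[stage])
                out["ihc_scored"] = scored
                out["ihc_summary"] = summary
                scored.to_csv(outdir / "ihc_calls.csv", index=False)
                summary.to_csv(outdir / "ihc_summary.csv", index=False)
                counts[stage] = {"neurons": len(scored)}
                all_results.append(res)
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        log.info("stage %s: done (%s)", stage, counts.get(stage))

    results = pd.concat(all_results, ignore_index=True) if all_results else pd.DataFrame()
    out["results"] = results
    results.to_csv(outdir / "results.csv", index=False)
    with open(outdir / "runlog.json", "w") as fh:
        json.dump({
            "seed": config.seed,
            "stages": list(config.stages),
            "config": config.to_dict(),
            "record_counts": counts,
        }, fh, indent=2, default=str)
    return out
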