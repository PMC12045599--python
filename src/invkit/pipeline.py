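"""End-to-end analysis drivers and the multi-stage pipeline runner.

The central driver, :func:`run_subset_share_study`, reproduces the full
subset-share experiment from simulation: it simulates reciprocal
capture / co-capture fields, segments mitochondria, measures per-cell
fluorescence, applies the responder filter, computes cytoplasmic losses and
derives the subset-share statistic — the fraction of one vesicle population
(INVs) occupied by the other (ATG9A-flavor vesicles).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import invkit
from invkit import io as invio
from invkit.capture_quant import (FieldImage, LossResult, build_masks,
                                  compute_ratios, cytoplasmic_loss,
                                  measure_field)
from invkit.errors import StageError
from invkit.kinetics_pools import (PoolEstimate, Trace, fit_single_exponential,
                                   pool_shares, tau_covariation)
from invkit.proteomics_enrichment import (differential_enrichment,
                                          log2_transform, impute_missing,
                                          read_quant_table)
from invkit.puncta_golgi import quantify_puncta
from invkit.reporting import superplot_summary
from invkit.synthetic_data import (CHANNEL_INDEX, SimulationConfig,
                                   simulate_fixed_capture_pair)

__all__ = ["SubsetShareStudy", "quantify_capture_pair",
           "run_subset_share_study", "run_pipeline"]


def _derive_seed(base: int, *branch: int) -> int:
    h = hashlib.sha256(("/".join(map(str, (base, *branch)))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _roles_for(config: SimulationConfig) -> dict[str, int]:
    fkbp = config.fkbp_channel
    poi = "B" if fkbp == "A" else "A"
    return {"fkbp_marker": CHANNEL_INDEX[fkbp],
            "poi": CHANNEL_INDEX[poi],
            "mitotrap": CHANNEL_INDEX["mitotrap"]}


def quantify_capture_pair(
    pre: np.ndarray,
    post: np.ndarray,
    roles: dict[str, int],
    replicate: str | int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a pre/post fixed-cell pair: segmentation, measurement, ratios.

    Mitochondria are segmented from the post (treated) MitoTrap channel; the
    same masks measure both timepoints.  Returns ``(treated, reference)``
    relocalization records; the responder filter applies to the treated
    records only (the rule is defined on post-treatment cells).
    """
    mito_chan = post[roles["mitotrap"]]
    masks = build_masks(mito_chan)
    post_field = FieldImage(post, roles)
    pre_field = FieldImage(pre, roles)
    post_meas = measure_field(post_field, masks, replicate=replicate,
                              condition="rapalog")
    pre_meas = measure_field(pre_field, masks, replicate=replicate,
                             condition="control")
    treated = compute_ratios(post_meas, mode="fixed",
                             apply_responder_filter=True)
    reference = compute_ratios(pre_meas, mode="fixed",
                               apply_responder_filter=False)
    for df in (treated, reference):
        df["replicate"] = replicate
    return treated, reference


@dataclass
class SubsetShareStudy:
    """Result of the simulated capture / co-capture subset-share experiment."""

    max_loss: LossResult             # direct capture: loss of the INV marker
    co_loss: LossResult              # co-capture: loss of the same marker
    estimate: PoolEstimate
    n_cells: int                     # analysed (responder) cells per condition arm
    records: pd.DataFrame

    @property
    def subset_share(self) -> float:
        return self.estimate.subset_share_raw


def run_subset_share_study(
    base_config: SimulationConfig | None = None,
    n_cells: int = 12,
    n_seeds: int = 3,
    base_seed: int = 1,
    image_shape: tuple[int, int] = (480, 640),
) -> SubsetShareStudy:
    """Simulate and quantify the reciprocal capture experiment end to end.

    For each seed (an experimental replicate) two fields are simulated: a
    direct-capture field where the INV marker (channel A) is FKBP-tagged, and
    a co-capture field where the ATG9A-like marker (channel B) is tagged.
    The pipeline then recovers the cytoplasmic loss of channel A in both
    arms and forms the subset share ``co_loss / max_loss``.
    """
    base = base_config or SimulationConfig()
    base = base.replace(n_cells=n_cells, image_shape=image_shape)
    direct_t, direct_r, co_t, co_r = [], [], [], []
    all_records = []
    for rep in range(n_seeds):
        for arm, fkbp in (("direct", "A"), ("co", "B")):
            cfg = base.replace(fkbp_channel=fkbp,
                               seed=_derive_seed(base_seed, rep, fkbp == "B"))
            pre, post, _ = simulate_fixed_capture_pair(cfg)
            treated, reference = quantify_capture_pair(
                pre, post, _roles_for(cfg), replicate=rep)
            for df, kind in ((treated, "treated"), (reference, "reference")):
                df = df.assign(arm=arm, kind=kind)
                all_records.append(df)
                {"direct": {"treated": direct_t, "reference": direct_r},
                 "co": {"treated": co_t, "reference": co_r}}[arm][kind].append(df)
    cat = lambda dfs: pd.concat(dfs, ignore_index=True)
    # direct arm: the INV marker is the FKBP channel; co arm: it is the POI
    max_loss = cytoplasmic_loss(cat(direct_t), cat(direct_r),
                                channel="fkbp_marker")
    co_loss = cytoplasmic_loss(cat(co_t), cat(co_r), channel="poi")
    estimate = pool_shares(max_loss.grand_mean, co_loss.grand_mean)
    records = cat(all_records)
    n_analysed = int(records.query(
        "arm == 'direct' and kind == 'treated' and channel == 'fkbp_marker' "
        "and responder")["cell_id"].count())
    return SubsetShareStudy(max_loss=max_loss, co_loss=co_loss,
                            estimate=estimate, n_cells=n_analysed,
                            records=records)


# ---------------------------------------------------------------------------
# multi-stage pipeline
# ---------------------------------------------------------------------------

def _stage_simulate_fixed(params: dict, outdir: Path, seed: int) -> dict:
    cfg = SimulationConfig(**{**params.get("simulation", {}), "seed": seed})
    pre, post, gt = simulate_fixed_capture_pair(cfg)
    roles = _roles_for(cfg)
    invio.write_field(outdir / "pre.tiff", FieldImage(pre, roles, cfg.pixel_size))
    invio.write_field(outdir / "post.tiff", FieldImage(post, roles, cfg.pixel_size))
    gt.vesicles.to_csv(outdir / "ground_truth_vesicles.csv", index=False)
    gt.cells.to_csv(outdir / "ground_truth_cells.csv", index=False)
    invio.write_mask(outdir / "ground_truth_cells.tiff", gt.cell_labels)
    return {"n_cells": cfg.n_cells, "subset_share_true": gt.subset_share}


def _stage_quantify_capture(params: dict, outdir: Path, seed: int) -> dict:
    pre = invio.read_field(Path(params["pre"]))
    post = invio.read_field(Path(params["post"]))
    treated, reference = quantify_capture_pair(
        pre.data, post.data, post.roles, replicate=params.get("replicate", 0))
    treated.to_csv(outdir / "ratios_treated.csv", index=False)
    reference.to_csv(outdir / "ratios_reference.csv", index=False)
    return {"n_treated": len(treated), "n_reference": len(reference)}


def _stage_subset_share(params: dict, outdir: Path, seed: int) -> dict:
    study = run_subset_share_study(
        n_cells=params.get("n_cells", 12),
        n_seeds=params.get("n_seeds", 3),
        base_seed=seed,
        image_shape=tuple(params.get("image_shape", (480, 640))),
    )
    study.records.to_csv(outdir / "records.csv", index=False)
    result = {
        "max_loss_percent": study.max_loss.grand_mean,
        "co_loss_percent": study.co_loss.grand_mean,
        "subset_share": study.estimate.subset_share,
        "subset_share_percent_rounded_ten": study.estimate.percent_rounded_ten,
        "full_capture": study.estimate.full_capture,
        "n_cells": study.n_cells,
    }
    (outdir / "pools.json").write_text(json.dumps(result, indent=1))
    return result


def _stage_kinetics(params: dict, outdir: Path, seed: int) -> dict:
    traces = pd.read_csv(params["traces"])
    need = {"cell_id", "channel", "t", "F"}
    if not need <= set(traces.columns):
        raise StageError(f"trace CSV needs columns {sorted(need)}")
    t_on = float(params.get("t_on", 0.0))
    fits = []
    for (cid, ch), grp in traces.groupby(["cell_id", "channel"]):
        fit = fit_single_exponential(
            Trace(grp["t"].to_numpy(), grp["F"].to_numpy(), t_on,
                  cell_id=cid, channel=ch))
        fits.append({"cell_id": cid, "channel": ch, "tau": fit.tau,
                     "f_base": fit.f_base, "f_plateau": fit.f_plateau,
                     "rss": fit.rss, "converged": fit.converged})
    fits = pd.DataFrame(fits)
    fits.to_csv(outdir / "fits.csv", index=False)
    out = {"n_fits": len(fits), "n_converged": int(fits["converged"].sum())}
    wide = fits[fits["converged"]].pivot_table(index="cell_id",
                                               columns="channel", values="tau")
    if wide.shape[1] == 2 and len(wide.dropna()) >= 2:
        cov = tau_covariation(wide.dropna().to_numpy())
        out["tau_slope"] = cov.slope
        out["tau_r_squared"] = cov.r_squared
    return out


def _stage_pools(params: dict, outdir: Path, seed: int) -> dict:
    est = pool_shares(float(params["max_loss"]), float(params["co_loss"]),
                      float(params.get("tolerance", 0.1)))
    result = {"subset_share": est.subset_share,
              "subset_share_raw": est.subset_share_raw,
              "percent_rounded_ten": est.percent_rounded_ten,
              "full_capture": est.full_capture,
              "rendered": est.render()}
    (outdir / "pools.json").write_text(json.dumps(result, indent=1))
    return result


def _stage_puncta(params: dict, outdir: Path, seed: int) -> dict:
    stack = invio.read_mask(Path(params["stack"])).astype(float)
    ps = quantify_puncta(stack, tuple(params["voxel_size"]),
                         float(params.get("min_volume", 0.012)))
    ps.puncta.to_csv(outdir / "puncta.csv", index=False)
    ps.per_cell.to_csv(outdir / "puncta_per_cell.csv", index=False)
    return {"count": ps.count, "mean_volume_um3": ps.mean_volume}


def _stage_proteomics(params: dict, outdir: Path, seed: int) -> dict:
    table = read_quant_table(Path(params["table"]))
    table = impute_missing(log2_transform(table),
                           shift=float(params.get("shift", 1.8)),
                           width=float(params.get("width", 0.3)),
                           seed=seed)
    enr = differential_enrichment(table, params["condition_a"],
                                  params["condition_b"],
                                  fc_cut=float(params.get("fc_cut", 2.0)),
                                  p_cut=float(params.get("p_cut", 0.05)))
    enr.to_csv(outdir / "enrichment.csv", index=False)
    return {"n_proteins": len(enr),
            "n_enriched": int((enr["class"] == "pink").sum())}


def _stage_report(params: dict, outdir: Path, seed: int) -> dict:
    cells = pd.read_csv(params["cells"])
    data = superplot_summary(cells, value=params.get("value", "value"),
                             factors=tuple(params.get("factors", ["condition"])),
                             replicate=params.get("replicate", "replicate"))
    data.group_summary.to_csv(outdir / "superplot_summary.csv", index=False)
    out = {"n_groups": len(data.group_summary)}
    if data.anova is not None:
        data.anova.to_csv(outdir / "anova.csv")
        out["anova_p"] = {str(k): float(v)
                         for k, v in data.anova["PR(>F)"].dropna().items()}
    if data.tukey is not None:
        data.tukey.to_csv(outdir / "tukey.csv", index=False)
    return out


_STAGES = {
    "simulate-fixed": _stage_simulate_fixed,
    "quantify-capture": _stage_quantify_capture,
    "subset-share": _stage_subset_share,
    "kinetics": _stage_kinetics,
    "pools": _stage_pools,
    "puncta": _stage_puncta,
    "proteomics": _stage_proteomics,
    "report": _stage_report,
}


def run_pipeline(config_path, outdir=None, seed: int | None = None) -> Path:
    """Execute the stages named in a YAML config; returns the output directory.

    The config is a mapping with a ``stages`` list (each entry a mapping with
    a ``name`` and stage parameters) and optional global ``seed`` / ``outdir``
    keys.  Stage names are validated before any stage runs.  Each stage
    writes into its own subdirectory; a ``provenance.json`` records the
    config hash, seed and package version.
    """
    config_path = Path(config_path)
    cfg = invio.load_config(config_path)
    stages = cfg.get("stages")
    if not stages:
        raise StageError("config declares no stages")
    unknown = [s.get("name") for s in stages if s.get("name") not in _STAGES]
    if unknown:
        raise StageError(f"unknown stage name(s): {unknown}; "
                         f"known: {sorted(_STAGES)}")
    out = Path(outdir or cfg.get("outdir", "invkit_output"))
    out.mkdir(parents=True, exist_ok=True)
    run_seed = seed if seed is not None else int(cfg.get("seed", 0))
    results, provenance = {}, []
    for i, stage in enumerate(stages):
        name = stage["name"]
        params = {k: v for k, v in stage.items() if k != "name"}
        stage_dir = out / f"{i:02d}_{name}"
        stage_dir.mkdir(exist_ok=True)
        try:
            res = _STAGES[name](params, stage_dir, _derive_seed(run_seed, i))
        except (KeyError, FileNotFoundError) as exc:
            raise StageError(f"stage {name!r}: missing input: {exc}") from exc
        results[f"{i:02d}_{name}"] = res
        provenance.append({"stage": name, "params": params,
                           "outputs": sorted(p.name for p in stage_dir.iterdir())})
    meta = {
        "config": config_path.name,
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "seed": run_seed,
        "invkit_version": invkit.__version__,
        "stages": provenance,
        "results": results,
    }
    (out / "provenance.json").write_text(json.dumps(meta, indent=1, default=str))
    return out
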