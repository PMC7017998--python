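"""End-to-end orchestration: panel -> filter -> tax -> fit -> summaries.

Every stage reads and writes plain CSV/JSON so any intermediate can be
audited; the run manifest records input hashes, the seed, package version
and record counts at each filter stage.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ingest, panel as panel_mod, summaries, tax
from .model import ModelSpec, TrendModel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str = "tobtax_out"
    panel: str | None = None            # existing panel CSV, or None to simulate
    synthetic: dict | None = None       # PanelConfig overrides for simulation
    segment_map: str | None = None      # CSV path; None -> generator's own map
    timeline: str = "uk"                # "uk" or a YAML file of regime rows
    inflation_index: str | None = None  # CSV path; None -> flat index
    responses: tuple = ("pps_real", "netrev_real")
    seed: int = 0
    n_draws: int = 10000
    threshold_pct: float = 10.0
    vat_mode: str = "exclusive"
    snap: str = "next_month"
    window_pre: tuple = summaries.PRE_WINDOW
    window_post: tuple = summaries.POST_WINDOW
    event_months: tuple = ()
    basis_dim: int = 10
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("responses", "window_pre", "window_post", "event_months"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for attr in ("panel", "segment_map", "inflation_index"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config path for {attr!r} does not exist: {p}")
        if cfg.timeline != "uk" and not Path(cfg.timeline).exists():
            raise PipelineError(f"timeline file does not exist: {cfg.timeline}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_timeline(spec: str, snap: str = "next_month"):
    if spec == "uk":
        return tax.uk_timeline(snap=snap)
    with open(spec) as fh:
        rows = yaml.safe_load(fh)
    return tax.timeline_from_dicts(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "inputs": {}, "counts": {}, "outputs": []}

    def _record_output(path: Path):
        manifest["outputs"].append(str(path))

    # --- stage 1: obtain panel
    try:
        if config.panel is not None:
            panel_path = Path(config.panel)
            manifest["inputs"]["panel"] = _sha256(panel_path)
            records = ingest.read_panel(panel_path)
            seg_map = (ingest.SegmentMap.from_csv(config.segment_map)
                       if config.segment_map else None)
            if config.segment_map:
                manifest["inputs"]["segment_map"] = _sha256(Path(config.segment_map))
        else:
            pc = panel_mod.config_from_dict(
                {**(config.synthetic or {}), "seed": config.seed})
            records = panel_mod.generate_panel(pc)
            panel_path = out / "panel.csv"
            ingest.write_panel(records, panel_path)
            _record_output(panel_path)
            map_df = panel_mod.segment_map_frame(pc)
            map_path = out / "segment_map.csv"
            map_df.to_csv(map_path, index=False)
            _record_output(map_path)
            seg_map = ingest.SegmentMap.from_frame(map_df)
            records = ingest.read_panel(panel_path)
    except Exception as exc:
        raise PipelineError(f"stage 'ingest' failed: {exc}") from exc
    manifest["counts"]["raw"] = len(records)
    manifest["counts"]["invalid_rows"] = len(records.attrs.get("invalid_rows", []))

    # --- stage 2: segments + distribution filter
    try:
        if seg_map is not None:
            records = ingest.assign_segments(records, seg_map)
        fr = ingest.apply_distribution_filter(records, config.threshold_pct)
    except Exception as exc:
        raise PipelineError(f"stage 'filter' failed: {exc}") from exc
    records = fr.kept
    manifest["counts"].update({
        "dropped_missing_distribution": fr.n_dropped_missing,
        "dropped_below_threshold": fr.n_dropped_below,
        "analysed": len(records),
    })

    # --- stage 3: taxes + deflation (taxes on nominal prices first)
    try:
        timeline = load_timeline(config.timeline, config.snap)
        n_months = int(records["month"].max())
        index = (tax.InflationIndex.from_csv(config.inflation_index)
                 if config.inflation_index else tax.InflationIndex.flat(n_months))
        records = tax.attach_tax_columns(records, timeline, index,
                                         vat_mode=config.vat_mode)
        taxed_path = out / "taxed_panel.csv"
        records.to_csv(taxed_path, index=False)
        _record_output(taxed_path)
    except Exception as exc:
        raise PipelineError(f"stage 'tax' failed: {exc}") from exc

    # --- stage 4: models + summaries per response
    results_by_response = {}
    for response in config.responses:
        try:
            model = TrendModel(records, spec=ModelSpec(
                response=response, basis_dim=config.basis_dim))
            res = model.fit()
        except Exception as exc:
            raise PipelineError(f"stage 'fit:{response}' failed: {exc}") from exc
        results_by_response[response] = res
        res.save_json(out / f"model_{response}.json")
        _record_output(out / f"model_{response}.json")
        (out / f"summary_{response}.txt").write_text(res.summary() + "\n")

        try:
            draws = res.simulate_params(config.n_draws, seed=config.seed + 1)
            frames = []
            all_series = {}
            for stratum in summaries.STRATA:
                ser = summaries.weighted_average_series(res, records, draws,
                                                       stratum=stratum)
                all_series.update({f"{stratum}:{k}": v for k, v in ser.items()})
                frames += [s.to_frame() for s in ser.values()]
            wap_path = out / f"wap_{response}.csv"
            pd.concat(frames, ignore_index=True).to_csv(wap_path, index=False)
            _record_output(wap_path)

            seg_series = {k.split(":", 1)[1]: v for k, v in all_series.items()
                          if k.startswith("segment:")}
            type_series = {k.split(":", 1)[1]: v for k, v in all_series.items()
                           if k.startswith("product_type:")}
            gap_pairs = [("FM premium", "FM subvalue"),
                         ("FM value", "FM subvalue"),
                         ("FM subvalue", "RYO premium")]
            gaps = []
            for a, b in gap_pairs:
                if a in seg_series and b in seg_series:
                    gaps.append(summaries.gap_series(seg_series[a], seg_series[b]))
            if {"FM", "RYO"} <= set(type_series):
                gaps.append(summaries.gap_series(type_series["FM"],
                                                 type_series["RYO"]))
            if gaps:
                gap_path = out / f"gaps_{response}.csv"
                pd.concat([g.to_frame() for g in gaps],
                          ignore_index=True).to_csv(gap_path, index=False)
                _record_output(gap_path)

            comps = []
            for label, s in seg_series.items():
                try:
                    comps.append(summaries.growth_comparison(
                        s, config.window_pre, config.window_post))
                except ValueError:
                    logger.warning("growth window not covered for %r", label)
            if comps:
                rows = [{"label": c.label,
                         "pre": c.pre.estimate, "pre_lo": c.pre.lo,
                         "pre_hi": c.pre.hi, "post": c.post.estimate,
                         "post_lo": c.post.lo, "post_hi": c.post.hi,
                         "diff": c.diff_estimate, "diff_lo": c.diff_lo,
                         "diff_hi": c.diff_hi} for c in comps]
                growth_path = out / f"growth_{response}.csv"
                pd.DataFrame(rows).to_csv(growth_path, index=False)
                _record_output(growth_path)

            if response.startswith("netrev") and config.event_months:
                shift_frames = []
                for em in config.event_months:
                    shift_frames.append(summaries.shift_analysis(
                        seg_series, event_month=em))
                shift_path = out / f"shift_{response}.csv"
                pd.concat(shift_frames, ignore_index=True).to_csv(
                    shift_path, index=False)
                _record_output(shift_path)

            if config.plots:
                from . import plots
                fig = plots.trend_plot(seg_series, ylabel=response)
                fig.savefig(out / f"trend_{response}.png", dpi=120)
                if comps:
                    fig = plots.forest_plot(comps, title=response)
                    fig.savefig(out / f"forest_{response}.png", dpi=120)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'summarize:{response}' failed: {exc}") from exc

    manifest["rho"] = {r: results_by_response[r].rho for r in results_by_response}
    manifest["aic"] = {r: results_by_response[r].aic for r in results_by_response}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
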