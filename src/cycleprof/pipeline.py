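"""End-to-end orchestration of the profiling cascade.

gate -> fingerprint -> CCI -> hit selection -> viability filter -> potency
filter -> clustering, with every intermediate persisted as CSV and a
machine-readable run manifest.  Re-running an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from cycleprof.cci import Fingerprint, cci_table, dmso_reference, select_hits
from cycleprof.clustering import (
    complete_linkage,
    distance_matrix,
    heatmap_export,
    tree_to_newick,
    zscore_transform,
)
from cycleprof.errors import CycleprofError, ValidationError
from cycleprof.gating import gate_well, zprime_factor
from cycleprof.io import (
    read_dose_table,
    read_viability_table,
    write_phase_table,
)
from cycleprof.synthcyto import PlateMap, read_events_long
from cycleprof.viability import (
    cytotoxic_hits,
    effective_concentration,
    fit_four_param_logistic,
    percent_viability,
)

log = logging.getLogger("cycleprof")


@dataclass
class RunConfig:
    """Cascade constants and input/output paths for one screen run."""

    seed: int = 0
    cci_cutoff: float = 10.0
    sd_k: float = 3.0
    ec50_max_uM: float = 20.0
    bins: int = 128
    gate_k: float = 2.5
    zscore_axis: int = 1
    events: str | None = None
    plate_map: str | None = None
    viability: str | None = None
    doses: str | None = None
    out_dir: str = "cycleprof_out"

    def __post_init__(self) -> None:
        for name in ("cci_cutoff", "sd_k", "ec50_max_uM", "gate_k"):
            if getattr(self, name) <= 0 and name != "cci_cutoff":
                raise ValidationError(f"{name} must be positive")
        if self.cci_cutoff < 0:
            raise ValidationError("cci_cutoff must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ScreenResult:
    phases: pd.DataFrame
    cci: pd.DataFrame
    cci_hits: list[str]
    viability_pct: pd.DataFrame
    viability_hits: list[str]
    fits: pd.DataFrame
    potent_hits: list[str]
    qc: pd.DataFrame
    cluster_order: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


class StageFailure(CycleprofError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_screen(config: RunConfig) -> ScreenResult:
    """Execute the full cascade from persisted inputs.

    Hits narrow monotonically: viability hits are drawn from the CCI hits
    and potency-qualified hits from the viability hits.  Every applied
    cutoff is logged with its configured value, and a FAILED marker is
    written to the manifest if a stage aborts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from cycleprof import __version__

    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    stage = "setup"

    def _finish_stage(name: str) -> None:
        manifest["stages"][name] = "ok"

    try:
        # ------------------------------------------------ gating
        stage = "gate"
        plate_map = PlateMap.from_csv(config.plate_map)
        events = read_events_long(config.events)
        fingerprints: list[Fingerprint] = []
        well_ids: list[str] = []
        dmso_fps: list[Fingerprint] = []
        for wid in plate_map.non_empty_wells():
            if wid not in events:
                continue
            wr = plate_map.wells[wid]
            frac = gate_well(events[wid], bins=config.bins, k=config.gate_k)
            name = wr.compound if wr.role == "compound" else (
                "DMSO" if wr.role == "dmso_control" else "POS"
            )
            fp = Fingerprint.from_fractions(name, frac)
            fingerprints.append(fp)
            well_ids.append(wid)
            if wr.role == "dmso_control":
                dmso_fps.append(fp)
        phases_path = out / "phases.csv"
        write_phase_table(fingerprints, phases_path, well_ids=well_ids)
        manifest["outputs"]["phases"] = str(phases_path)
        phases_df = pd.read_csv(phases_path, dtype={"well_id": str})
        _finish_stage(stage)

        # ------------------------------------------------ CCI
        stage = "cci"
        ref = dmso_reference(dmso_fps)
        compound_fps = [
            fp for fp, wid in zip(fingerprints, well_ids)
            if plate_map.wells[wid].role == "compound"
        ]
        cci_df = cci_table(compound_fps, ref, cutoff=config.cci_cutoff)
        log.info("CCI cutoff applied: %s (strict >)", config.cci_cutoff)
        cci_hits = select_hits(
            dict(zip(cci_df["compound"], cci_df["cci"])), cutoff=config.cci_cutoff
        )
        cci_path = out / "cci.csv"
        cci_df.to_csv(cci_path, index=False, float_format="%.4f")
        manifest["outputs"]["cci"] = str(cci_path)
        _finish_stage(stage)

        # ------------------------------------------------ viability + QC
        stage = "viability"
        via_hits: list[str] = []
        via_df = pd.DataFrame(columns=["compound", "viability_pct"])
        qc_df = pd.DataFrame(columns=["mu_p", "sigma_p", "mu_n", "sigma_n", "zprime"])
        if config.viability:
            plate = read_viability_table(config.viability)
            dmso_rows = plate[plate["role"] == "dmso_control"]
            if len(dmso_rows) < 2:
                raise ValidationError("viability plate needs >= 2 DMSO wells")
            dmso_mean = float(dmso_rows["reading"].mean())
            comp_rows = plate[plate["role"] == "compound"]
            via_pct = {
                name: float(percent_viability(grp["reading"].to_numpy(), dmso_mean).mean())
                if grp.shape[0] > 1
                else float(percent_viability(float(grp["reading"].iloc[0]), dmso_mean))
                for name, grp in comp_rows.groupby("compound")
            }
            via_df = pd.DataFrame(
                {"compound": list(via_pct), "viability_pct": list(via_pct.values())}
            ).sort_values("compound", ignore_index=True)
            dmso_pct = percent_viability(dmso_rows["reading"].to_numpy(), dmso_mean)
            log.info("viability cutoff applied: > %s sample SD below DMSO", config.sd_k)
            hit_df = cytotoxic_hits(
                {c: v for c, v in via_pct.items() if c in set(cci_hits)},
                dmso_pct,
                k=config.sd_k,
            )
            via_hits = [c for c in cci_hits if c in set(hit_df["compound"])]
            pos_rows = plate[plate["role"] == "positive_control"]
            if pos_rows.shape[0] >= 2:
                qc = zprime_factor(pos_rows["reading"], dmso_rows["reading"])
                qc_df = pd.DataFrame([asdict(qc)])
            via_path = out / "viability.csv"
            via_df.to_csv(via_path, index=False, float_format="%.4f")
            qc_path = out / "qc.csv"
            qc_df.to_csv(qc_path, index=False, float_format="%.6f")
            manifest["outputs"].update(viability=str(via_path), qc=str(qc_path))
        _finish_stage(stage)

        # ------------------------------------------------ potency
        stage = "potency"
        potent: list[str] = []
        fits_df = pd.DataFrame(
            columns=["compound", "ec50_uM", "hill", "top", "bottom", "rss",
                     "converged", "ec90_uM"]
        )
        if config.doses:
            doses = read_dose_table(config.doses)
            eligible = via_hits if config.viability else cci_hits
            rows = []
            for name in eligible:
                sub = doses[doses["compound"] == name]
                if sub.empty:
                    continue
                fit = fit_four_param_logistic(
                    sub["dose_uM"].to_numpy(float), sub["response"].to_numpy(float)
                )
                ec90 = effective_concentration(fit, 90.0) if fit.converged else np.nan
                rows.append({"compound": name, "ec50_uM": fit.ec50, "hill": fit.hill,
                             "top": fit.top, "bottom": fit.bottom, "rss": fit.rss,
                             "converged": fit.converged, "ec90_uM": ec90})
                if fit.converged and fit.ec50 < config.ec50_max_uM:
                    potent.append(name)
            log.info("potency cutoff applied: EC50 < %s uM (strict <)", config.ec50_max_uM)
            if rows:
                fits_df = pd.DataFrame(rows)
            fits_path = out / "fits.csv"
            fits_df.to_csv(fits_path, index=False, float_format="%.6g")
            manifest["outputs"]["fits"] = str(fits_path)
        _finish_stage(stage)

        # ------------------------------------------------ clustering
        stage = "cluster"
        cluster_order = None
        final = potent if config.doses else (via_hits if config.viability else cci_hits)
        final_fps = [fp for fp in compound_fps if fp.compound in set(final)]
        if len(final_fps) >= 2:
            dist = distance_matrix(final_fps)
            tree = complete_linkage(dist)
            raw = np.array([fp.as_tuple() for fp in final_fps])
            z = zscore_transform(raw, axis=config.zscore_axis)
            cluster_order = heatmap_export(
                tree, z, [fp.compound for fp in final_fps],
                out_prefix=str(out / "cluster"),
            )
            merges = pd.DataFrame(tree.merges, columns=["a", "b", "height"])
            merges.to_csv(out / "cluster_merges.csv", index=False, float_format="%.6g")
            (out / "cluster.nwk").write_text(
                tree_to_newick(tree, [fp.compound for fp in final_fps]) + "\n"
            )
            manifest["outputs"]["cluster"] = str(out / "cluster_matrix.csv")
        _finish_stage(stage)

    except Exception as exc:
        manifest["stages"][stage] = "FAILED"
        manifest["error"] = f"{stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageFailure(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ScreenResult(
        phases=phases_df,
        cci=cci_df,
        cci_hits=cci_hits,
        viability_pct=via_df,
        viability_hits=via_hits,
        fits=fits_df,
        potent_hits=potent,
        qc=qc_df,
        cluster_order=cluster_order,
        manifest=manifest,
    )


def supplementary_cascade(
    fingerprints: list[Fingerprint],
    viability_pct: Mapping[str, float] | None = None,
    dmso_viability_pct=None,
    ec50_uM: Mapping[str, float] | None = None,
    cci_cutoff: float = 10.0,
    sd_k: float = 3.0,
    viability_50: float = 50.0,
    ec50_max_uM: float = 20.0,
    reference: Fingerprint | None = None,
) -> dict:
    """Replay the published screen cascade over a pre-gated results table.

    Computes per-compound CCIs against the DMSO reference (supplied, or the
    mean of rows named 'DMSO'), then the successive filter counts: CCI above
    the cutoff, viability more than k SD below DMSO, viability below 50%,
    and EC50 under the potency ceiling.
    """
    if reference is None:
        dmso_rows = [fp for fp in fingerprints if fp.compound.upper().startswith("DMSO")]
        if not dmso_rows:
            raise ValidationError("no DMSO rows and no explicit reference supplied")
        reference = dmso_reference(dmso_rows)
    drug_fps = [fp for fp in fingerprints if not fp.compound.upper().startswith("DMSO")]
    table = cci_table(drug_fps, reference, cutoff=cci_cutoff)
    ccis = dict(zip(table["compound"], table["cci"]))
    cci_hits = select_hits(ccis, cutoff=cci_cutoff)
    result = {"cci": ccis, "cci_hits": cci_hits, "n_cci_hits": len(cci_hits)}
    if viability_pct is not None and dmso_viability_pct is not None:
        sub = {c: viability_pct[c] for c in cci_hits if c in viability_pct}
        hits = cytotoxic_hits(sub, dmso_viability_pct, k=sd_k)
        via_hits = sorted(hits["compound"])
        result["viability_hits"] = via_hits
        result["n_viability_hits"] = len(via_hits)
        result["n_below_50pct"] = sum(1 for c in cci_hits if viability_pct.get(c, 100.0) < viability_50)
    if ec50_uM is not None:
        pool = result.get("viability_hits", cci_hits)
        potent = sorted(c for c in pool if c in ec50_uM and ec50_uM[c] < ec50_max_uM)
        result["potent_hits"] = potent
        result["n_potent_hits"] = len(potent)
    return result
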