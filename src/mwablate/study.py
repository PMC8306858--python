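"""Parametric ablation study: frequencies x breathing states.

Runs the coupled chain (dielectric properties -> EM solve -> transient
bioheat -> damage) for every requested combination of microwave frequency
and tissue state and collects the comparative summary quantities: final
peak temperature, saturation time, probe necrotic fraction, time to
complete necrosis, peak SAR with its axial location, and ablation-zone
morphology.  The default configuration is the four-frequency
(0.915/1.5/2/2.45 GHz), three-state (inflated/deflated/constant) sweep at
10 W for 600 s.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bioheat import BioheatParams, run_transient
from .damage import (
    ArrheniusParams,
    integrate_arrhenius,
    necrotic_fraction_curve,
    time_to_threshold,
    zone_morphology,
)
from .dielectrics import TissueState, get_properties
from .em import (
    CoaxPortSpec,
    assemble_helmholtz,
    build_material_map,
    compute_sar_profile,
    solve_field,
)
from .geometry import DomainGeometry, build_default_geometry, generate_grid

log = logging.getLogger("mwablate.study")

__all__ = ["StudyConfig", "RunResult", "StudyResult", "run_single", "run_study", "compare_states"]

MM = 1e-3


@dataclass(frozen=True)
class StudyConfig:
    """Study conditions; the defaults are the reference parametric sweep."""

    frequencies_hz: tuple = (0.915e9, 1.5e9, 2.0e9, 2.45e9)
    states: tuple = (
        TissueState.INFLATED,
        TissueState.DEFLATED,
        TissueState.CONSTANT,
    )
    input_power_w: float = 10.0
    duration_s: float = 600.0
    dt_s: float = 1.0
    store_every_s: float = 5.0
    h_fine: float = 0.1 * MM
    h_coarse: float = 0.75 * MM
    probe_r: float = 2.5 * MM  # slot-adjacent probe / axial-profile radius
    necrosis_level: float = 0.99  # "complete necrosis" convention
    output_dir: str | None = None
    write_fields: bool = False
    random_seed: int = 0  # reserved for fixture generation; physics is deterministic

    def __post_init__(self) -> None:
        if len(self.frequencies_hz) == 0 or len(self.states) == 0:
            raise ValueError("frequencies and states must be non-empty")
        if self.input_power_w <= 0 or self.duration_s <= 0:
            raise ValueError("power and duration must be > 0")

    def fast(self) -> "StudyConfig":
        """Coarsened settings for quick qualitative runs."""
        return replace(self, h_fine=0.25 * MM, h_coarse=1.5 * MM, dt_s=2.0)

    # -- config-file round trip ------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["states"] = [TissueState(s).value for s in self.states]
        d["frequencies_hz"] = list(self.frequencies_hz)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "states" in d:
            d["states"] = tuple(TissueState(s) for s in d["states"])
        if "frequencies_hz" in d:
            d["frequencies_hz"] = tuple(float(f) for f in d["frequencies_hz"])
        return cls(**d)


@dataclass
class RunResult:
    """Summary of one (frequency, state) simulation."""

    frequency_hz: float
    state: str
    T_max_final: float  # K
    saturation_time_s: float
    theta_probe_final: float
    time_to_full_necrosis_s: float
    SAR_max: float  # W/kg along the probe line
    SAR_max_z: float  # m
    absorbed_power_w: float
    reflected_power_w: float
    zone_area_m2: float
    zone_axial_m: float
    zone_radial_m: float
    zone_aspect: float


@dataclass
class StudyResult:
    """All per-combination records plus the configuration that produced them."""

    config: StudyConfig
    records: pd.DataFrame

    def record(self, frequency_hz: float, state) -> pd.Series:
        state = TissueState(state).value
        sel = self.records[
            (self.records.frequency_hz == frequency_hz)
            & (self.records.state == state)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique record for ({frequency_hz}, {state})")
        return sel.iloc[0]


def run_single(
    frequency_hz: float,
    state,
    config: StudyConfig = StudyConfig(),
    domain: DomainGeometry | None = None,
    bioheat: BioheatParams = BioheatParams(),
    arrhenius: ArrheniusParams = ArrheniusParams(),
    return_details: bool = False,
):
    """One coupled EM -> bioheat -> damage run; returns a :class:`RunResult`.

    With ``return_details=True`` also returns a dict holding the grid, the
    field solution, the temperature history and the damage field.
    """
    t0 = time.perf_counter()
    state = TissueState(state)
    domain = domain or build_default_geometry()
    grid = generate_grid(domain, config.h_fine, config.h_coarse)
    ant = domain.antenna

    sample = get_properties(state, frequency_hz)
    mat = build_material_map(grid, sample)
    port = CoaxPortSpec(
        power_w=config.input_power_w,
        frequency_hz=frequency_hz,
        r_in=ant.r_inner_conductor,
        r_out=ant.r_dielectric,
    )
    sol = solve_field(assemble_helmholtz(grid, mat, port), rho_tissue=bioheat.rho)
    t_em = time.perf_counter()

    probe = (config.probe_r, ant.slot_center_z)
    hist = run_transient(
        grid,
        bioheat,
        sol.Q_ext,
        duration=config.duration_s,
        dt=config.dt_s,
        store_every=config.store_every_s,
        probes=[probe],
    )
    t_th = time.perf_counter()

    dmg = integrate_arrhenius(hist, arrhenius)
    zone_morphology(dmg, grid)
    curve = necrotic_fraction_curve(hist, arrhenius, probe=probe)
    profile = compute_sar_profile(sol, grid, config.probe_r)
    imax = int(np.argmax(profile[:, 1]))

    rec = RunResult(
        frequency_hz=frequency_hz,
        state=state.value,
        T_max_final=hist.T_max_final,
        saturation_time_s=hist.saturation_time,
        theta_probe_final=float(curve[-1, 1]),
        time_to_full_necrosis_s=time_to_threshold(curve, config.necrosis_level),
        SAR_max=float(profile[imax, 1]),
        SAR_max_z=float(profile[imax, 0]),
        absorbed_power_w=sol.absorbed_power,
        reflected_power_w=sol.reflected_power,
        zone_area_m2=dmg.zone_area,
        zone_axial_m=dmg.axial_extent,
        zone_radial_m=dmg.radial_extent,
        zone_aspect=dmg.aspect_ratio,
    )
    log.info(
        "run f=%.3f GHz state=%s: EM %.1fs, thermal %.1fs, Tmax=%.1f K",
        frequency_hz / 1e9,
        state.value,
        t_em - t0,
        t_th - t_em,
        rec.T_max_final,
    )
    if return_details:
        return rec, {
            "grid": grid,
            "solution": sol,
            "history": hist,
            "damage": dmg,
            "necrosis_curve": curve,
            "sar_profile": profile,
        }
    return rec


def run_study(config: StudyConfig = StudyConfig(), **kwargs) -> StudyResult:
    """Run the full parametric sweep defined by ``config``.

    Runs execute in a fixed order (sorted by frequency, then state) so logs
    and outputs are deterministic.  Per-run failures are recorded and
    re-raised after the remaining combinations complete.  Extra keyword
    arguments pass through to :func:`run_single`.
    """
    combos = sorted(
        (f, TissueState(s)) for f in config.frequencies_hz for s in config.states
    )
    rows, failures = [], []
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for f, s in combos:
        try:
            if outdir and config.write_fields:
                rec, det = run_single(f, s, config, return_details=True, **kwargs)
                _write_run_artifacts(outdir, rec, det)
            else:
                rec = run_single(f, s, config, **kwargs)
            rows.append(asdict(rec))
        except Exception as exc:  # noqa: BLE001 - re-raised below
            log.error("run (%.3g Hz, %s) failed: %s", f, s.value, exc)
            failures.append(((f, s.value), exc))

    records = pd.DataFrame(rows)
    result = StudyResult(config=config, records=records)
    if outdir:
        records.to_csv(outdir / "summary.csv", index=False)
        manifest = asdict(config)
        manifest["states"] = [TissueState(s).value for s in config.states]
        manifest["package_version"] = _pkg_version
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if failures:
        combo, exc = failures[0]
        raise RuntimeError(
            f"{len(failures)} study run(s) failed; first: {combo}: {exc}"
        ) from exc
    return result


def _write_run_artifacts(outdir: Path, rec: RunResult, det: dict) -> None:
    from .io import write_hdf5, write_vtk

    tag = f"f{rec.frequency_hz / 1e9:.3f}GHz_{rec.state}"
    grid = det["grid"]
    sol, hist, dmg = det["solution"], det["history"], det["damage"]
    write_vtk(
        outdir / f"{tag}.vtk",
        grid,
        cell_data={"Q_ext_w_per_m3": sol.Q_ext, "SAR_w_per_kg": sol.SAR},
        point_data={"T_final_k": hist.final_field, "theta_d": dmg.theta_d},
    )
    write_hdf5(
        outdir / f"{tag}.h5",
        grid,
        datasets={
            "Q_ext": sol.Q_ext,
            "T_snapshots": hist.fields,
            "snapshot_times": hist.times,
            "alpha": dmg.alpha,
            "theta_d": dmg.theta_d,
        },
        attrs={"frequency_hz": rec.frequency_hz, "state": rec.state},
    )
    pd.DataFrame(
        {"t_s": hist.peak_times, "tmax_k": hist.peak_trace}
    ).to_csv(outdir / f"{tag}_peak_trace.csv", index=False)
    pd.DataFrame(
        det["necrosis_curve"], columns=["t_s", "theta_d"]
    ).to_csv(outdir / f"{tag}_necrosis.csv", index=False)
    pd.DataFrame(
        det["sar_profile"], columns=["z_m", "sar_w_per_kg"]
    ).to_csv(outdir / f"{tag}_sar_profile.csv", index=False)


def compare_states(result: StudyResult, quantities=("T_max_final", "SAR_max", "theta_probe_final")) -> pd.DataFrame:
    """Per-frequency relative differences (%) between state pairs.

    The percentage is ``|a - b| / max(a, b) * 100`` so the larger value is
    always the denominator and pairs are labelled explicitly.  Missing
    states are skipped with a warning.
    """
    rows = []
    df = result.records
    for f in sorted(df.frequency_hz.unique()):
        sub = df[df.frequency_hz == f].set_index("state")
        states = list(sub.index)
        for i, a in enumerate(states):
            for b in states[i + 1:]:
                row = {"frequency_hz": f, "pair": f"{a}_vs_{b}"}
                for q in quantities:
                    va, vb = float(sub.loc[a, q]), float(sub.loc[b, q])
                    denom = max(abs(va), abs(vb))
                    row[f"{q}_diff_pct"] = (
                        abs(va - vb) / denom * 100.0 if denom > 0 else 0.0
                    )
                rows.append(row)
        if len(states) < 2:
            log.warning("frequency %.3g Hz has fewer than two states", f)
    return pd.DataFrame(rows)
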