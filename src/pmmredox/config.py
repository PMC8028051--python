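"""End-to-end pipeline driver configured from a YAML/JSON file.

A run config names the species (state-set files or a synthetic block),
the two frame ensembles (trajectory files or synthetic-generation
blocks), and the thermodynamic constants. ``run_pipeline`` executes
generation/loading, per-frame PMM, and the redox summary, writing a
summary JSON, per-frame CSV tables and a plain-text log; everything is
deterministic given the config and its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .constants import D_MIN_DEFAULT, V_SHE_DEFAULT
from .errors import PmmRedoxError, ValidationError
from .pmm import PmmConfig, gap_series
from .qc_model import RedoxSpeciesPair, load_stateset
from .redox import RedoxEstimate, redox_estimate
from .synthetic import SolventSpec, generate_solvent_frames, make_synthetic_pair
from .trajectory_io import read_frames


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    species: dict
    ensembles: dict  # {"reduced": {...}, "oxidized": {...}}
    output_dir: str = "results/run"
    seed: int = 0
    pbc: bool = True
    d_min: float = D_MIN_DEFAULT
    on_singularity: str = "skip"
    n_blocks: int = 3
    v_she: float = V_SHE_DEFAULT
    n_electrons: int = 1
    gas_correction: Optional[dict] = None  # {"gas_vie_calc":, "gas_vie_exp":}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValidationError("config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        fails = []
        if not isinstance(self.species, dict) or (
            ("paths" in self.species) == ("synthetic" in self.species)
        ):
            fails.append("species must contain exactly one of 'paths'/'synthetic'")
        for name in ("reduced", "oxidized"):
            blk = self.ensembles.get(name)
            if not isinstance(blk, dict) or (
                ("trajectory" in blk) == ("synthetic" in blk)
            ):
                fails.append(
                    f"ensembles.{name} must contain exactly one of "
                    "'trajectory'/'synthetic'"
                )
        if self.v_she <= 0:
            fails.append("v_she must be > 0")
        if self.n_electrons < 1:
            fails.append("n_electrons must be >= 1")
        if self.gas_correction is not None and not (
            "gas_vie_calc" in self.gas_correction
            and "gas_vie_exp" in self.gas_correction
        ):
            fails.append("gas_correction needs gas_vie_calc and gas_vie_exp")
        if fails:
            raise ValidationError(fails)

    @property
    def pmm(self) -> PmmConfig:
        return PmmConfig(
            use_pbc=self.pbc, d_min=self.d_min, on_singularity=self.on_singularity
        )


def _derived_seed(base: int, stream: int) -> int:
    return int(np.random.SeedSequence([base, stream]).generate_state(1)[0] % 2**31)


def _build_pair(cfg: RunConfig) -> RedoxSpeciesPair:
    if "paths" in cfg.species:
        p = cfg.species["paths"]
        pair = RedoxSpeciesPair(
            red=load_stateset(p["red"]),
            ox_vertical=load_stateset(p["ox_vertical"]),
            ox_adiabatic=load_stateset(p["ox_adiabatic"]),
            gas_vie_calc=float(p.get("gas_vie_calc", float("nan"))),
            gas_vie_exp=p.get("gas_vie_exp"),
        )
        pair.validate()
        return pair
    blk = dict(cfg.species["synthetic"])
    blk.setdefault("seed", _derived_seed(cfg.seed, 0))
    if "dipole_shift_debye" in blk:
        from .constants import DEBYE_TO_E_NM

        blk["dipole_shift"] = float(blk.pop("dipole_shift_debye")) * DEBYE_TO_E_NM
    return make_synthetic_pair(**blk)


def _build_ensemble(cfg: RunConfig, name: str, pair: RedoxSpeciesPair):
    blk = cfg.ensembles[name]
    if "trajectory" in blk:
        t = blk["trajectory"]
        return read_frames(
            t["coords"],
            charge_table_path=t.get("charges"),
            qc_selection=t["qc_selection"],
            label=name,
            temperature=float(t.get("temperature", 300.0)),
            fmt=t.get("format"),
        )
    s = dict(blk["synthetic"])
    mode = s.pop("mode", "iid")
    n_frames = int(s.pop("n_frames"))
    kwargs = {
        k: s.pop(k)
        for k in ("burn_in_sweeps", "stride_sweeps", "trans_step", "max_rot")
        if k in s
    }
    s.setdefault("seed", _derived_seed(cfg.seed, 1 if name == "reduced" else 2))
    spec = SolventSpec(**s)
    # the oxidized ensemble is sampled around the relaxed cation, the
    # reduced ensemble around the neutral species
    species = pair.red if name == "reduced" else pair.ox_adiabatic
    qc_coords = species.coords + spec.box_edge / 2.0  # QC at the box center
    return generate_solvent_frames(
        spec,
        qc_coords,
        n_frames,
        mode=mode,
        qc_state_charges=species.states[0].atomic_charges
        if mode == "metropolis"
        else None,
        label=name,
        **kwargs,
    )


def run_pipeline(cfg: RunConfig) -> RedoxEstimate:
    """Execute the full pipeline and write artifacts to cfg.output_dir."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    status_path = outdir / "status.json"
    status_path.write_text('{"complete": false}\n')
    log_lines = [f"pmmredox {__version__}", f"seed {cfg.seed}"]
    try:
        pair = _build_pair(cfg)
        log_lines.append(f"species: {pair.red.species_label} "
                         f"({pair.red.n_atoms} atoms, {pair.red.n_states} states)")
        ens_red = _build_ensemble(cfg, "reduced", pair)
        ens_ox = _build_ensemble(cfg, "oxidized", pair)
        log_lines.append(
            f"frames: reduced {len(ens_red)}, oxidized {len(ens_ox)}"
        )
        vert_red, t_vr = gap_series(
            ens_red, pair, "vertical", cfg.pmm, return_table=True
        )
        adia_red, t_ar = gap_series(
            ens_red, pair, "adiabatic", cfg.pmm, return_table=True
        )
        adia_ox, t_ao = gap_series(
            ens_ox, pair, "adiabatic", cfg.pmm, return_table=True
        )
        gas_calc = gas_exp = None
        if cfg.gas_correction is not None:
            gas_calc = float(cfg.gas_correction["gas_vie_calc"])
            gas_exp = float(cfg.gas_correction["gas_vie_exp"])
        elif pair.gas_vie_exp is not None:
            gas_calc, gas_exp = pair.gas_vie_calc, pair.gas_vie_exp
        est = redox_estimate(
            vert_red, adia_red, adia_ox,
            n_electrons=cfg.n_electrons, v_she=cfg.v_she,
            n_blocks=cfg.n_blocks, gas_calc=gas_calc, gas_exp=gas_exp,
        )
        t_vr.to_csv(outdir / "frames_vertical_reduced.csv", index=False)
        t_ar.to_csv(outdir / "frames_adiabatic_reduced.csv", index=False)
        t_ao.to_csv(outdir / "frames_adiabatic_oxidized.csv", index=False)
        summary = {
            "version": __version__,
            "seed": cfg.seed,
            "v_she_V": cfg.v_she,
            "n_electrons": cfg.n_electrons,
            **{k: (round(v, 4) if isinstance(v, float) else v)
               for k, v in est.to_dict().items()},
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
            fh.write("\n")
        log_lines.append(
            f"skipped frames: reduced {est.n_skipped_red}, "
            f"oxidized {est.n_skipped_ox}"
        )
        log_lines.append("status: complete")
        status_path.write_text('{"complete": true}\n')
    finally:
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return est
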