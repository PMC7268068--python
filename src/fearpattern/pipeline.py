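"""End-to-end run: configuration, seeding, per-participant simulation and decoding.

A :class:`RunConfig` bundles every stage's parameters.  The master seed is
expanded through ``numpy.random.SeedSequence``: participant p draws the child
sequence ``SeedSequence(master).spawn(n_participants)[p]``, and each stage of
that participant (reinforcement assignment, per-hemisphere pattern basis and
noise, decoding, cross-decoding) consumes one grandchild in a fixed, documented
order, so any stage can be re-run in isolation and reproduced exactly.  The
trial order itself is shared across participants (one fixed, seeded
permutation), mirroring a design in which all participants receive the same
optimised sequence; reinforcement positions are redrawn per participant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import glm as glm_mod
from . import inference as inference_mod
from . import mvpa as mvpa_mod
from . import synth as synth_mod
from .containers import TrialBetaMatrix
from .design import DesignParams
from .synth import SynthParams

__all__ = [
    "GlmOptions",
    "MvpaOptions",
    "RunConfig",
    "PipelineResult",
    "participant_seeds",
    "simulate_participant",
    "run_pipeline",
    "make_demo_config",
]

logger = logging.getLogger("fearpattern")

HEMISPHERES = ("left", "right")

# fixed order in which each participant's grandchild seeds are consumed
_STAGES = ("reinforcement", "basis_left", "basis_right", "noise_left", "noise_right", "mvpa", "crossdecode")


@dataclass(frozen=True)
class GlmOptions:
    """Time-series mode options; ignored in beta mode."""

    mode: str = "beta"  # "beta": draw amplitudes directly; "timeseries": render + re-estimate
    tr: float = 2.5
    highpass_cutoff: float = 128.0
    oversample: int = 16
    scan_noise_sd: float = 0.0
    us_amp: float = 1.0

    def validate(self) -> None:
        if self.mode not in ("beta", "timeseries"):
            raise ValueError("glm.mode must be 'beta' or 'timeseries'")
        if self.tr <= 0:
            raise ValueError("glm.tr must be positive")
        if self.highpass_cutoff <= 0:
            raise ValueError("glm.highpass_cutoff must be positive")


@dataclass(frozen=True)
class MvpaOptions:
    n_perm: int = 1000
    n_subsample_reps: int = 100
    C: float = 1.0
    engine: str = "libsvm"

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("mvpa.n_perm must be >= 1")
        if self.n_subsample_reps < 1:
            raise ValueError("mvpa.n_subsample_reps must be >= 1")
        mvpa_mod.ClassifierSpec(C=self.C, engine=self.engine)  # reuses its validation

    def spec(self) -> mvpa_mod.ClassifierSpec:
        return mvpa_mod.ClassifierSpec(C=self.C, engine=self.engine)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a simulated group study."""

    n_participants: int = 20
    master_seed: int = 0
    design: DesignParams = field(default_factory=DesignParams)
    synth: SynthParams = field(default_factory=SynthParams)
    glm: GlmOptions = field(default_factory=GlmOptions)
    mvpa: MvpaOptions = field(default_factory=MvpaOptions)
    run_crossdecoding: bool = True

    def validate(self) -> None:
        problems = []
        if self.n_participants < 1:
            problems.append("n_participants must be >= 1")
        for name, obj in (("design", self.design), ("synth", self.synth),
                          ("glm", self.glm), ("mvpa", self.mvpa)):
            try:
                obj.validate()
            except ValueError as exc:
                problems.append(f"{name}: {exc}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["iti_set"] = list(self.design.iti_set)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            dd = dict(d["design"])
            if "iti_set" in dd:
                dd["iti_set"] = tuple(dd["iti_set"])
            d["design"] = DesignParams(**dd)
        if "synth" in d:
            d["synth"] = SynthParams(**d["synth"])
        if "glm" in d:
            d["glm"] = GlmOptions(**d["glm"])
        if "mvpa" in d:
            d["mvpa"] = MvpaOptions(**d["mvpa"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of result tables from one pipeline run."""

    decoding: pd.DataFrame
    crossdecoding: pd.DataFrame | None
    effects: pd.DataFrame | None
    crossdecoding_effects: pd.DataFrame | None
    config: RunConfig
    failed_participants: list[str]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": self.config.config_hash(), "master_seed": self.config.master_seed}
        for name, df in (
            ("decoding", self.decoding),
            ("crossdecoding", self.crossdecoding),
            ("effects", self.effects),
            ("crossdecoding_effects", self.crossdecoding_effects),
        ):
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "run_info.json").write_text(
            json.dumps({**stamp, "config": self.config.to_dict(),
                        "failed_participants": self.failed_participants}, indent=2)
        )
        (out / "report.txt").write_text(self.report())

    def report(self) -> str:
        """Plain-text summary of the run's group-level results."""
        lines = [
            f"fearpattern run (config {self.config.config_hash()}, "
            f"seed {self.config.master_seed})",
            "",
        ]
        if len(self.decoding):
            lines.append("mean excess accuracy per condition:")
            cell = self.decoding.groupby(["context", "complexity"])["excess_accuracy"].mean()
            lines.extend(f"  {ctx:>16s} {cx:<8s} {v:+.4f}" for (ctx, cx), v in cell.items())
            lines.append("")
        if self.effects is not None:
            lines.append("factorial model on excess accuracies:")
            for _, row in self.effects.iterrows():
                lines.append(
                    f"  {row['effect']:<36s} F({row['df1']:.0f},{row['df2']:.0f}) = "
                    f"{row['F']:6.2f}  p = {row['p']:.4f}"
                )
            lines.append("")
        if self.crossdecoding_effects is not None:
            lines.append("cross-decoding model (stimulus class x direction):")
            for _, row in self.crossdecoding_effects.iterrows():
                lines.append(
                    f"  {row['effect']:<36s} F({row['df1']:.0f},{row['df2']:.0f}) = "
                    f"{row['F']:6.2f}  p = {row['p']:.4f}"
                )
            lines.append("")
        if self.failed_participants:
            lines.append(f"excluded participants: {', '.join(self.failed_participants)}")
        return "\n".join(lines) + "\n"


def participant_seeds(master_seed: int, n_participants: int) -> list[dict[str, np.random.SeedSequence]]:
    """Named grandchild seed sequences per participant (see module docstring)."""
    children = np.random.SeedSequence(master_seed).spawn(n_participants)
    out = []
    for child in children:
        grandchildren = child.spawn(len(_STAGES))
        out.append(dict(zip(_STAGES, grandchildren)))
    return out


def _shared_design(config: RunConfig) -> design_mod.ExperimentDesign:
    """Trial order shared by all participants; derived from the design seed."""
    return design_mod.generate_design(config.design)


def simulate_participant(
    config: RunConfig,
    participant_index: int,
    seeds: dict[str, np.random.SeedSequence] | None = None,
    base_design: design_mod.ExperimentDesign | None = None,
) -> dict[str, TrialBetaMatrix]:
    """Simulate one participant's per-hemisphere trial beta matrices.

    Hemispheres are modelled as two independent voxel sets with shared
    synthesis parameters.  In time-series mode the betas are re-estimated
    from a rendered BOLD run through the trial-wise GLM.
    """
    if seeds is None:
        seeds = participant_seeds(config.master_seed, config.n_participants)[participant_index]
    if base_design is None:
        base_design = _shared_design(config)
    pid = f"sub-{participant_index + 1:02d}"
    reinf_seed = int(seeds["reinforcement"].generate_state(1)[0] % (2**31))
    design = design_mod.assign_reinforcement(base_design, reinf_seed)

    out: dict[str, TrialBetaMatrix] = {}
    for hemi in HEMISPHERES:
        basis_seed = int(seeds[f"basis_{hemi}"].generate_state(1)[0] % (2**31))
        basis = synth_mod.make_pattern_basis(
            dataclasses.replace(config.synth, seed=basis_seed)
        )
        noise_rng = np.random.default_rng(seeds[f"noise_{hemi}"])
        if config.glm.mode == "beta":
            betas = synth_mod.simulate_betas(
                design, basis, config.synth, rng=noise_rng, participant=pid, hemisphere=hemi
            )
        else:
            sim = synth_mod.simulate_timeseries(
                design,
                basis,
                config.synth,
                tr=config.glm.tr,
                scan_noise_sd=config.glm.scan_noise_sd,
                us_amp=config.glm.us_amp,
                oversample=config.glm.oversample,
                rng=noise_rng,
            )
            X = glm_mod.build_design_matrix(
                design,
                config.glm.tr,
                highpass_cutoff=config.glm.highpass_cutoff,
                oversample=config.glm.oversample,
            )
            betas = glm_mod.estimate_trial_betas(
                sim.data, X, design=design, participant=pid, hemisphere=hemi
            )
        out[hemi] = betas
    return out


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Simulate the group, decode every condition, and run the factorial models.

    Participants are processed independently; a failure in one is logged and
    excluded rather than aborting the run.  Group inference is attempted only
    when at least two participants succeeded.
    """
    config.validate()
    all_seeds = participant_seeds(config.master_seed, config.n_participants)
    base_design = _shared_design(config)
    spec = config.mvpa.spec()

    decoding_rows = []
    cross_rows = []
    failed: list[str] = []
    for p in range(config.n_participants):
        pid = f"sub-{p + 1:02d}"
        try:
            betas = simulate_participant(config, p, all_seeds[p], base_design)
            mvpa_rng = np.random.default_rng(all_seeds[p]["mvpa"])
            for hemi in HEMISPHERES:
                decoding_rows.append(
                    mvpa_mod.decode_participant(
                        betas[hemi],
                        n_perm=config.mvpa.n_perm,
                        n_subsample_reps=config.mvpa.n_subsample_reps,
                        spec=spec,
                        rng=mvpa_rng,
                    )
                )
            if config.run_crossdecoding:
                cross_rng = np.random.default_rng(all_seeds[p]["crossdecode"])
                for hemi in HEMISPHERES:
                    cross_rows.append(
                        mvpa_mod.cross_decode_participant(
                            betas[hemi],
                            n_perm=config.mvpa.n_perm,
                            n_subsample_reps=config.mvpa.n_subsample_reps,
                            spec=spec,
                            rng=cross_rng,
                        )
                    )
        except Exception:
            logger.exception("participant %s failed; excluding from group results", pid)
            failed.append(pid)

    decoding = pd.concat(decoding_rows, ignore_index=True) if decoding_rows else pd.DataFrame()
    crossdecoding = (
        pd.concat(cross_rows, ignore_index=True) if cross_rows else None
    )

    effects = None
    cross_effects = None
    n_ok = decoding["participant"].nunique() if len(decoding) else 0
    if n_ok >= 2:
        effects = inference_mod.factorial_accuracy_model(decoding)
        if crossdecoding is not None and len(crossdecoding):
            cross_effects = inference_mod.crossdecoding_model(crossdecoding)

    result = PipelineResult(
        decoding=decoding,
        crossdecoding=crossdecoding,
        effects=effects,
        crossdecoding_effects=cross_effects,
        config=config,
        failed_participants=failed,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def make_demo_config(**overrides) -> RunConfig:
    """A miniature configuration exercising every stage in well under a minute."""
    base = dict(
        n_participants=2,
        master_seed=7,
        synth=SynthParams(n_voxels=50),
        mvpa=MvpaOptions(n_perm=50, n_subsample_reps=5),
    )
    base.update(overrides)
    return RunConfig(**base)
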