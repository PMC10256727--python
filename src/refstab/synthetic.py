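"""Synthetic Ct data with the study design and known ground truth.

The generator emulates a methoprene-bioassay screening design: 2 body
parts x 4 colonies x 5 sampling days (0D, 1D, 5D, 10D, 15D), one Ct per
gene per sample.  A sample's Ct for gene i is

    Ct = baseline_i + bodypart_offset_i * [thorax]
         + colony_effect_c + day_effects_i[d] + eps

with one Gaussian colony effect per colony (shared by all genes and
days — colonies respond as units, which also induces the between-gene
Ct correlation the pair-selection gate probes) and independent Gaussian
replicate noise per well.  Noise in the second body part is inflated by
a configurable factor, mirroring the larger Ct spread seen in
thorax + abdomen tissue.  All-zero ``day_effects`` define a stable
reference; a nonzero profile plants a treatment drift.

Everything is reproducible from the config seed; no global random state
is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .ct_io import CtMatrix
from . import published

__all__ = ["GeneSpec", "SimConfig", "simulate_ct", "study_like_config"]

DAYS = ("0D", "1D", "5D", "10D", "15D")
BODY_PARTS = ("head", "thorax_abdomen")


@dataclass
class GeneSpec:
    """Generative parameters of one simulated assay."""

    name: str
    baseline_ct: float
    noise_sd: float = 0.3
    day_effects: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    bodypart_offset: float = 0.0
    efficiency_pct: float = 100.0

    def __post_init__(self) -> None:
        self.day_effects = tuple(float(x) for x in self.day_effects)
        if not 10 < self.baseline_ct < 38:
            raise ValueError(f"baseline Ct {self.baseline_ct} outside (10, 38)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def is_stable(self) -> bool:
        return all(e == 0 for e in self.day_effects)


@dataclass
class SimConfig:
    """Full generative configuration for one synthetic dataset."""

    genes: list[GeneSpec]
    colonies: int = 4
    days: tuple[str, ...] = DAYS
    body_parts: tuple[str, ...] = BODY_PARTS
    colony_sd: float = 0.3
    thorax_noise_scale: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.days = tuple(self.days)
        self.body_parts = tuple(self.body_parts)
        if self.colonies < 1 or not self.genes:
            raise ValueError("need >= 1 colony and >= 1 gene")
        if self.colony_sd < 0:
            raise ValueError("colony_sd must be >= 0")
        for g in self.genes:
            if len(g.day_effects) != len(self.days):
                raise ValueError(
                    f"gene {g.name!r}: day_effects length {len(g.day_effects)} "
                    f"!= number of days {len(self.days)}"
                )

    # -- plain-text (YAML) round trip -------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        d["genes"] = [asdict(g) for g in self.genes]
        for g in d["genes"]:
            g["day_effects"] = list(g["day_effects"])
        d["days"] = list(self.days)
        d["body_parts"] = list(self.body_parts)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        d["genes"] = [GeneSpec(**g) for g in d["genes"]]
        return cls(**d)


def simulate_ct(cfg: SimConfig, seed: int | None = None) -> tuple[CtMatrix, dict]:
    """Draw one synthetic dataset; returns (CtMatrix, ground-truth labels).

    The ground-truth sidecar names the planted stable genes, drifting
    genes, and (by convention) flags the lowest-noise stable gene as the
    designed best reference.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    colony_effect = rng.normal(0.0, cfg.colony_sd, size=cfg.colonies)

    sample_ids, meta_rows = [], []
    for part_i, part in enumerate(cfg.body_parts):
        for c in range(cfg.colonies):
            for d, day in enumerate(cfg.days):
                sid = f"{part}_c{c + 1}_{day}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "colony": f"c{c + 1}", "body_part": part, "day": day}
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    ct = pd.DataFrame(index=[g.name for g in cfg.genes], columns=sample_ids, dtype=float)
    for g in cfg.genes:
        for sid, row in meta.iterrows():
            part_i = cfg.body_parts.index(row["body_part"])
            c = int(row["colony"][1:]) - 1
            d = cfg.days.index(row["day"])
            scale = cfg.thorax_noise_scale if part_i == 1 else 1.0
            ct.loc[g.name, sid] = (
                g.baseline_ct
                + g.bodypart_offset * part_i
                + colony_effect[c]
                + g.day_effects[d]
                + rng.normal(0.0, g.noise_sd * scale)
            )

    stable = [g.name for g in cfg.genes if g.is_stable]
    drifting = [g.name for g in cfg.genes if not g.is_stable]
    best = min(
        (g for g in cfg.genes if g.is_stable),
        key=lambda g: g.noise_sd,
        default=None,
    )
    truth = {
        "stable_genes": stable,
        "drifting_genes": drifting,
        "designed_best": best.name if best else None,
        "seed": int(cfg.seed if seed is None else seed),
    }
    return CtMatrix(ct, meta), truth


def study_like_config(seed: int = 20230609) -> SimConfig:
    """The frozen default scenario mirroring the study's qualitative structure.

    Nine genes in the 2 x 4 x 5 design (360 Ct cells): seven stable
    reference candidates (one, the designed winner, with visibly lower
    replicate noise), one U6-like candidate that drifts with treatment
    day and is noisier than the rest, and one let-7-like target whose
    expression rises monotonically over the time-course (Ct falls).  The
    drifting candidate's expression moves in the same direction as the
    target's, so normalizing the target to it flattens the real trend —
    the failure mode unstable references cause in practice.
    """
    eff = published.EFFICIENCY_PERCENT
    zero = (0.0,) * 5
    genes = [
        GeneSpec("novel-m0649-3p", 24.0, 0.1, zero, 0.2, eff["novel-m0649-3p"]),
        GeneSpec("miR-193-3p", 24.5, 0.4, zero, 0.5, eff["miR-193-3p"]),
        GeneSpec("miR-971-5p", 25.0, 0.4, zero, -0.4, eff["miR-971-5p"]),
        GeneSpec("miR-3049-5p", 27.0, 0.4, zero, 0.3, eff["miR-3049-5p"]),
        GeneSpec("miR-216-5p", 26.0, 0.4, zero, 0.6, eff["miR-216-5p"]),
        GeneSpec("miR-7-3p", 23.0, 0.4, zero, -0.5, eff["miR-7-3p"]),
        GeneSpec("miR-2788-3p", 25.5, 0.4, zero, 0.4, eff["miR-2788-3p"]),
        GeneSpec(
            "U6", 22.0, 0.6, (0.0, -0.5, -1.0, -1.5, -2.0), 0.8, eff["U6"]
        ),
        GeneSpec(
            "let-7-3p", 28.0, 0.4, (0.0, -0.7, -1.4, -2.1, -2.8), 0.3, eff["let-7-3p"]
        ),
    ]
    return SimConfig(genes=genes, seed=seed)
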