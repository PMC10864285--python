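"""Synthetic inputs with planted ground truth for the whole pipeline.

Three generators mirror the three data sources the screen consumes:

* ``simulate_expression`` — a replicate expression matrix with
  per-replicate detection flags. Intensities are log-normal around a
  base level; planted genes get a multiplicative fold-change in chosen
  tissues; a replicate is "present" when its intensity clears a
  detection floor.

* ``simulate_cross`` — an egg-level model of the nondisjunction test
  cross. Each egg independently derives from an X-nondisjunction event
  with probability ``d``; nondisjunction ova are diplo-X or nullo-X with
  equal probability, sperm contribute X or B^S Y with equal probability,
  and the inviable zygotes (XXX, YO) are removed before tallying. The
  estimator's factor-2 correction is therefore tested against the
  mechanism rather than assumed: the scored NDJ frequency is a
  consistent estimator of ``d``.

* ``simulate_screen`` — a screen-results table in the summary dialect
  ("STERILE" / "<total>, <k> NDJ") with per-gene truth.

All draws flow through one ``numpy.random.Generator``; identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .microarray import TissuePanel
from .types import ProbeSetProfile, RawTally

# Default study conditions for the expression generator: four biological
# replicates per tissue, log-normal noise with sd 0.25 on the log scale,
# and four-fold planted enrichment.
DEFAULT_TISSUES = ("whole_body", "ovary", "testis", "cns",
                   "head", "midgut", "fat_body")
DEFAULT_N_REPLICATES = 4
DEFAULT_BASE_MEAN = 100.0
DEFAULT_LOG_SD = 0.25
DEFAULT_FOLD = 4.0

_GROUP_TISSUES = {
    "ovary_only": ("ovary",),
    "ovary_cns": ("ovary", "cns"),
    "ovary_testis": ("ovary", "testis"),
    "ovary_cns_testis": ("ovary", "cns", "testis"),
}


@dataclass
class SimConfig:
    """Serializable description of one synthetic dataset."""

    seed: int = 0
    n_genes: int = 200
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = DEFAULT_N_REPLICATES
    base_mean: float = DEFAULT_BASE_MEAN
    log_sd: float = DEFAULT_LOG_SD
    detection_floor: Optional[float] = None  # default: base_mean
    # gene_id -> (group label, fold-change)
    planted_effects: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    # gene_id -> {"sterile_mvd1": bool, "sterile_mata": bool,
    #             "d": float, "brood_mean": float}
    screen_truth: Dict[str, Dict] = field(default_factory=dict)
    # gene_id -> {"gc": float, "soma": float, "fc": float}
    sc_truth: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(seed: int = 0, n_genes: int = 200,
                   n_planted: int = 20) -> SimConfig:
    """Planted-truth config used across the test-bench: ``n_planted``
    genes with 4-fold ovary-centred enrichment (cycled over the four
    groups), half of them sterile in one driver and half with an
    elevated NDJ egg fraction, among otherwise flat genes."""
    groups = list(_GROUP_TISSUES)
    planted = {}
    screen = {}
    for i in range(n_planted):
        gid = f"g{i:04d}"
        planted[gid] = (groups[i % len(groups)], DEFAULT_FOLD)
        if i % 2 == 0:
            screen[gid] = {"sterile_mvd1": True, "sterile_mata": False,
                           "d": 0.0, "brood_mean": 400.0}
        else:
            screen[gid] = {"sterile_mvd1": False, "sterile_mata": False,
                           "d": 0.10, "brood_mean": 400.0}
    return SimConfig(seed=seed, n_genes=n_genes, planted_effects=planted,
                     screen_truth=screen)


# --------------------------------------------------------------------------
# expression matrix
# --------------------------------------------------------------------------

def simulate_expression(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[ProbeSetProfile], pd.DataFrame]:
    """Generate replicate expression profiles plus a truth table.

    Returns ``(profiles, truth)`` where ``truth`` has columns gene_id,
    gene_symbol, true_group (not_selected for unplanted genes), and
    fold.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    floor = cfg.detection_floor if cfg.detection_floor is not None else cfg.base_mean
    log_base = np.log(cfg.base_mean)

    profiles: List[ProbeSetProfile] = []
    truth_rows = []
    for i in range(cfg.n_genes):
        gid = f"g{i:04d}"
        group, fold = cfg.planted_effects.get(gid, ("not_selected", 1.0))
        boosted = _GROUP_TISSUES.get(group, ())
        intensities = {}
        present = {}
        for tissue in cfg.tissues:
            mu = log_base + (np.log(fold) if tissue in boosted else 0.0)
            vals = np.exp(rng.normal(mu, cfg.log_sd, size=cfg.n_replicates))
            intensities[tissue] = [float(v) for v in vals]
            present[tissue] = [bool(v >= floor) for v in vals]
        profiles.append(ProbeSetProfile(
            probe_id=f"p_{gid}", gene_id=gid, gene_symbol=f"CG{9000 + i}",
            intensities=intensities, present=present))
        truth_rows.append({"gene_id": gid, "gene_symbol": f"CG{9000 + i}",
                           "true_group": group, "fold": fold})
    return profiles, pd.DataFrame(truth_rows)


def expression_frame(profiles: Sequence[ProbeSetProfile]) -> pd.DataFrame:
    """Wide matrix with ``<tissue>.rep<k>`` and ``<tissue>.present<k>``."""
    rows = []
    for p in profiles:
        row = {"probe_id": p.probe_id, "gene_id": p.gene_id,
               "gene_symbol": p.gene_symbol}
        for tissue, vals in p.intensities.items():
            flags = p.present.get(tissue, [True] * len(vals))
            for k, (v, f) in enumerate(zip(vals, flags), start=1):
                row[f"{tissue}.rep{k}"] = v
                row[f"{tissue}.present{k}"] = "P" if f else "A"
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cross simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSim:
    """One simulated brood: survivors, and the egg-level bookkeeping."""

    tally: RawTally
    n_eggs: int
    n_inviable: int

    @property
    def n_survivors(self) -> int:
        return self.tally.total


def simulate_cross(
    d: float,
    brood_mean: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> CrossSim:
    """Simulate one brood of the nondisjunction test cross.

    ``d`` is the fraction of eggs deriving from X nondisjunction;
    ``brood_mean`` the Poisson mean of the egg number. Expected
    surviving progeny is ``(1 - d/2) * brood_mean`` because half of the
    exceptional zygotes (XXX, YO) die.
    """
    if not (0 <= d < 1):
        raise ValueError(f"d must be in [0, 1), got {d}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_eggs = int(rng.poisson(brood_mean))
    n_ndj = int(rng.binomial(n_eggs, d))
    n_normal = n_eggs - n_ndj

    # normal ova: X; sperm X -> XX daughter, sperm Y -> X/B^S Y son
    xx = int(rng.binomial(n_normal, 0.5))
    xy = n_normal - xx

    # exceptional ova: diplo-X or nullo-X, each then meeting X or Y sperm
    diplo = int(rng.binomial(n_ndj, 0.5))
    nullo = n_ndj - diplo
    xxx = int(rng.binomial(diplo, 0.5))      # dies
    xxy = diplo - xxx                        # survives (X/X/B^S Y daughter)
    xo = int(rng.binomial(nullo, 0.5))       # survives (X/O son)
    yo = nullo - xo                          # dies

    tally = RawTally(xx_females=xx, bs_males=xy, xo_males=xo, xxy_females=xxy)
    return CrossSim(tally=tally, n_eggs=n_eggs, n_inviable=xxx + yo)


# --------------------------------------------------------------------------
# screen table
# --------------------------------------------------------------------------

def simulate_screen(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a screen table in the summary dialect plus truth labels.

    One shRNA line per gene with screen truth; MVD1 and mata cells are
    either "STERILE" (per truth) or a simulated tally serialized as
    "<adjusted total>, <events> NDJ". Truth records the generative NDJ
    egg fraction and sterility flags.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    rows = []
    truth_rows = []
    for gid in sorted(cfg.screen_truth):
        spec = cfg.screen_truth[gid]
        d = float(spec.get("d", 0.0))
        brood = float(spec.get("brood_mean", 400.0))
        cells = {}
        for driver, key in (("mvd1", "sterile_mvd1"), ("mata", "sterile_mata")):
            if spec.get(key, False):
                cells[driver] = "STERILE"
            else:
                sim = simulate_cross(d, brood, rng=rng)
                t = sim.tally
                cells[driver] = f"{t.adjusted_total}, {t.ndj_events} NDJ"
        rows.append({
            "gene_id": gid, "gene_symbol": gid,
            "human_ortholog": "notfound", "mouse_ortholog": "notfound",
            "stock_id": f"SIM{gid[1:]}", "mvd1": cells["mvd1"],
            "mata": cells["mata"], "no_stage14": "", "tub_gal4": "",
        })
        truth_rows.append({
            "gene_id": gid,
            "sterile": bool(spec.get("sterile_mvd1") or spec.get("sterile_mata")),
            "d": d, "brood_mean": brood,
        })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# single-cell table
# --------------------------------------------------------------------------

DEFAULT_STAGE_MAP = {
    "germline_1": "gc", "germline_2": "gc", "germline_3": "gc",
    "soma_1": "soma", "soma_2": "soma",
    "follicle_1": "fc", "follicle_2": "fc", "follicle_3": "fc",
}


def simulate_single_cell(
    cfg: SimConfig,
    stage_map: Mapping[str, str] = DEFAULT_STAGE_MAP,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Long (gene_id, stage, value) table around per-cluster truth means.

    Genes without sc truth get equal means in all clusters.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    rows = []
    for i in range(cfg.n_genes):
        gid = f"g{i:04d}"
        means = cfg.sc_truth.get(gid, {"gc": 1.0, "soma": 1.0, "fc": 1.0})
        for stage, cluster in stage_map.items():
            value = float(rng.gamma(4.0, means.get(cluster, 1.0) / 4.0))
            rows.append({"gene_id": gid, "stage": stage, "value": value})
    return pd.DataFrame(rows)


def write_simulation(cfg: SimConfig, outdir) -> Dict[str, str]:
    """Write matrix, screen table, single-cell table, and truth.json."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    profiles, expr_truth = simulate_expression(cfg, rng)
    screen, screen_truth = simulate_screen(cfg, rng)
    sc = simulate_single_cell(cfg, rng=rng)

    paths = {
        "matrix": str(out / "matrix.tsv"),
        "screen": str(out / "screen.tsv"),
        "single_cell": str(out / "single_cell.tsv"),
        "truth": str(out / "truth.json"),
    }
    expression_frame(profiles).to_csv(paths["matrix"], sep="\t", index=False)
    screen.to_csv(paths["screen"], sep="\t", index=False)
    sc.to_csv(paths["single_cell"], sep="\t", index=False)
    truth = {
        "config": cfg.to_dict(),
        "expression": expr_truth.to_dict(orient="records"),
        "screen": screen_truth.to_dict(orient="records"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
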