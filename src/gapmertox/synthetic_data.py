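"""Seeded generators for synthetic study data.

Every stage of the pipeline can be exercised without the original
screening-campaign files.  The generators emulate the *structure* of that
campaign: a long target pre-mRNA; panels of tiled gapmers (reverse
complements of target windows, 14-20 nt, LNA flanks totalling 3-9 nt,
distributed over disjoint target regions -- 313 regions for the 1,645-ASO
training panel, 44 for the 148-ASO test panel, 7 for the 19-ASO validation
panel); calcium-oscillation scores that depend linearly on base
composition plus Gaussian noise, truncated at 0; mouse tolerability scores
that decrease monotonically with the underlying (noiseless) sequence
score through a logistic link, decomposed into five behavioral category
scores for 4-6 mice per group; Poisson-spike FLIPR traces; and a random
transcriptome for off-target screening.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .calcium_assay import DEFAULT_PROTOCOL, FliprProtocol, FliprTrace
from .designer import Transcriptome
from .features import feature_table
from .gapmer import AsoPanel, AsoSequence, reverse_complement, write_panel
from .scoring_model import PARAM_NAMES, linear_scores

#: default generating coefficients: the qualitative pattern of the fitted
#: model (p_G strongly negative, p_A the largest positive weight) with an
#: intercept placing typical scores on the 0-200 percent-of-control scale
#: such that roughly 60% of tiled ASOs fall in the acceptable tolerability
#: class under the default logistic link (the split the screening campaign
#: reports).
DEFAULT_TRUE_PARAMS = {
    "p_A": 3.0,
    "p_T": 1.0,
    "p_C": 1.5,
    "p_G": -8.0,
    "p_3": 1.0,
    "intercept": 102.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped simulation settings.

    Panel sizes and region counts mirror the screening campaign (1,645
    training / 148 test / 19 validation ASOs over 313 / 44 / 7 disjoint
    target regions); ASO lengths 14-20 nt with 3-9 LNA-modified
    nucleotides split between the two flanks.  ``calcium_noise_sd`` (25
    percent-of-control units) and the logistic tolerability link
    ``20 * logistic(-(score - 70) / 15)`` are calibration conventions of
    this generator, not measured values.
    """

    train_size: int = 1645
    test_size: int = 148
    validation_size: int = 19
    train_regions: int = 313
    test_regions: int = 44
    validation_regions: int = 7
    length_range: tuple[int, int] = (14, 20)
    flank_total_range: tuple[int, int] = (3, 9)
    true_params: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_PARAMS))
    calcium_noise_sd: float = 25.0
    link_midpoint: float = 70.0
    link_scale: float = 15.0
    link_max: float = 20.0
    tolerability_noise_sd: float = 2.0
    mice_range: tuple[int, int] = (4, 6)
    premrna_length: int = 9500
    gc_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("train_size", "test_size", "validation_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.calcium_noise_sd < 0 or self.tolerability_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.link_scale <= 0:
            raise ValueError("link_scale must be positive (monotone link)")


def simulate_target_premrna(
    length: int,
    gc_fraction: float = 0.5,
    seed: Optional[int] = 0,
) -> str:
    """Random target pre-mRNA (DNA letters) with the requested expected GC
    fraction."""
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def tile_asos(
    target: str,
    n_asos: int,
    n_regions: int,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = 0,
    id_prefix: str = "aso",
) -> AsoPanel:
    """Tile a panel of gapmers over disjoint regions of a target sequence.

    The target is split into ``n_regions`` contiguous, nonoverlapping
    blocks; ASOs are assigned to regions round-robin, and each is the
    reverse complement of a random window (length drawn from the configured
    range) inside its region.  LNA flanks are drawn with 3-9 modified
    nucleotides in total, split between the 5' and 3' ends.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    lmin, lmax = config.length_range
    region_len = len(target) // n_regions
    if region_len < lmax:
        raise ValueError(
            f"target too short: regions of {region_len} nt cannot hold "
            f"{lmax}-nt ASOs"
        )
    asos = []
    annotations = []
    for i in range(n_asos):
        region = i % n_regions
        start0 = region * region_len
        length = int(rng.integers(lmin, lmax + 1))
        offset = int(rng.integers(0, region_len - length + 1))
        window = target[start0 + offset : start0 + offset + length]
        bases = reverse_complement(window)
        total_lna = int(
            rng.integers(config.flank_total_range[0], config.flank_total_range[1] + 1)
        )
        five = int(rng.integers(1, total_lna))  # both flanks non-empty
        three = total_lna - five
        lna = tuple(j < five or j >= length - three for j in range(length))
        asos.append(
            AsoSequence(id=f"{id_prefix}{i + 1:05d}", bases=bases, lna=lna)
        )
        annotations.append(
            {"region": region, "target_start": start0 + offset, "target_end": start0 + offset + length}
        )
    ann = pd.DataFrame(
        annotations, index=pd.Index([a.id for a in asos], name="id")
    )
    return AsoPanel(asos, ann)


def true_scores(panel: AsoPanel, params=None) -> pd.Series:
    """Noiseless linear sequence scores of a panel under generating
    coefficients (default :data:`DEFAULT_TRUE_PARAMS`)."""
    params = params or DEFAULT_TRUE_PARAMS
    return pd.Series(
        linear_scores(feature_table(panel), params),
        index=pd.Index(panel.ids, name="id"),
        name="true_score",
    )


def simulate_calcium_scores(
    panel: AsoPanel,
    params=None,
    noise_sd: float = 25.0,
    seed: Optional[int] = 0,
    cap: Optional[float] = None,
) -> pd.Series:
    """Measured calcium-oscillation scores: the linear sequence score plus
    Gaussian noise, truncated below at 0 (optionally capped)."""
    rng = np.random.default_rng(seed)
    base = true_scores(panel, params).to_numpy()
    scores = base + rng.normal(0.0, noise_sd, size=len(base))
    scores = np.maximum(scores, 0.0)
    if cap is not None:
        scores = np.minimum(scores, cap)
    return pd.Series(
        scores, index=pd.Index(panel.ids, name="id"), name="calcium_score"
    )


def _decompose_total(total: int, rng: np.random.Generator) -> list[int]:
    """Random composition of an integer total into five category scores,
    each at most 4."""
    cats = [0] * 5
    for _ in range(total):
        open_cats = [k for k in range(5) if cats[k] < 4]
        cats[int(rng.choice(open_cats))] += 1
    return cats


def simulate_tolerability(
    calcium_scores: pd.Series,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Group-mean tolerability scores and per-mouse category decompositions.

    The latent severity of each ASO is a monotone-decreasing logistic link
    of its (calcium or sequence) score,
    ``link_max * logistic(-(score - link_midpoint) / link_scale)``; each of
    the 4-6 mice per group adds Gaussian noise, the per-mouse total is
    rounded and clamped to [0, 20] and decomposed into five category scores
    (each <= 4), and per-mouse totals are averaged per group.

    Returns ``(group_means, mice)`` where ``mice`` has one row per mouse
    with columns id, mouse, cat1..cat5, total.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    means = {}
    rows = []
    for aso_id, score in calcium_scores.items():
        latent = config.link_max * expit(
            -(score - config.link_midpoint) / config.link_scale
        )
        n_mice = int(rng.integers(config.mice_range[0], config.mice_range[1] + 1))
        totals = []
        for m in range(n_mice):
            val = latent + rng.normal(0.0, config.tolerability_noise_sd)
            total = int(np.clip(round(val), 0, 20))
            cats = _decompose_total(total, rng)
            totals.append(total)
            rows.append(
                {
                    "id": aso_id,
                    "mouse": m + 1,
                    **{f"cat{k + 1}": cats[k] for k in range(5)},
                    "total": total,
                }
            )
        means[aso_id] = float(np.mean(totals))
    group_means = pd.Series(means, name="tolerability_score").rename_axis("id")
    return group_means, pd.DataFrame(rows)


def simulate_flipr_trace(
    spike_rate: float,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    protocol: FliprProtocol = DEFAULT_PROTOCOL,
    seed: Optional[int] = 0,
    baseline: float = 100.0,
    decay_tau: float = 3.0,
    well: str = "",
    treatment: str = "",
) -> FliprTrace:
    """Protocol-segmented synthetic FLIPR trace: a flat baseline plus
    Poisson-timed calcium spikes (instant rise, exponential decay with time
    constant ``decay_tau``) and Gaussian read noise."""
    if spike_rate < 0:
        raise ValueError("spike_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = protocol.total_s
    t = np.arange(n, dtype=float)
    values = np.full(n, baseline, dtype=float)
    n_spikes = rng.poisson(spike_rate * n)
    spike_times = np.sort(rng.uniform(0, n, size=n_spikes))
    for ts in spike_times:
        mask = t >= ts
        values[mask] += amplitude * np.exp(-(t[mask] - ts) / decay_tau)
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=n)
    return FliprTrace(
        values=np.maximum(values, 0.0),
        protocol=protocol,
        well=well,
        treatment=treatment,
    )


def simulate_transcriptome(
    n_transcripts: int = 50,
    length_range: tuple[int, int] = (150, 300),
    gc_fraction: float = 0.5,
    seed: Optional[int] = 0,
) -> Transcriptome:
    """Random transcriptome with unique ids for off-target screening."""
    if n_transcripts < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    records = {}
    for i in range(n_transcripts):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        records[f"tx{i + 1:04d}"] = simulate_target_premrna(
            length, gc_fraction, seed=int(rng.integers(0, 2**31 - 1))
        )
    return Transcriptome(records)


@dataclass
class SyntheticStudy:
    """All in-memory pieces of a simulated study."""

    target: str
    train: AsoPanel
    test: AsoPanel
    validation: AsoPanel
    transcriptome: Transcriptome
    config: GeneratorConfig


def simulate_study(
    config: Optional[GeneratorConfig] = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a full study: target, train/test/validation panels with
    measured calcium scores, tolerability on the test and validation
    panels, and a transcriptome.

    Tolerability is driven by each ASO's *noiseless* sequence score (the
    in-vivo response tracks the underlying sequence effect, not the assay
    noise), while measured calcium scores add assay noise; both derive from
    the same generating coefficients.
    """
    config = config or GeneratorConfig()
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=10)
    target = simulate_target_premrna(
        config.premrna_length, config.gc_fraction, seed=int(seeds[0])
    )
    panels = {}
    for name, size, regions, s_tile, s_ca, s_tol, prefix in [
        ("train", config.train_size, config.train_regions, 1, 2, 3, "trn"),
        ("test", config.test_size, config.test_regions, 4, 5, 6, "tst"),
        (
            "validation",
            config.validation_size,
            config.validation_regions,
            7,
            8,
            9,
            "val",
        ),
    ]:
        panel = tile_asos(
            target,
            size,
            regions,
            config,
            seed=int(seeds[s_tile]),
            id_prefix=prefix,
        )
        calcium = simulate_calcium_scores(
            panel,
            config.true_params,
            config.calcium_noise_sd,
            seed=int(seeds[s_ca]),
        )
        panel.annotations["calcium_score"] = calcium
        if name in ("test", "validation"):
            latent = true_scores(panel, config.true_params)
            tol, _mice = simulate_tolerability(
                latent, config, seed=int(seeds[s_tol])
            )
            panel.annotations["tolerability_score"] = tol
        panels[name] = panel
    txome = simulate_transcriptome(seed=int(root.integers(0, 2**31 - 1)))
    return SyntheticStudy(
        target=target,
        train=panels["train"],
        test=panels["test"],
        validation=panels["validation"],
        transcriptome=txome,
        config=config,
    )


def write_study(study: SyntheticStudy, outdir: Union[str, Path]) -> dict[str, Path]:
    """Materialise a study as TSV panels, a target FASTA, a transcriptome
    FASTA and the generator configuration; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("train", "test", "validation"):
        path = outdir / f"{name}.tsv"
        write_panel(getattr(study, name), path)
        paths[name] = path
    target_path = outdir / "target.fa"
    target_path.write_text(f">target\n{study.target}\n")
    paths["target"] = target_path
    tx_path = outdir / "transcriptome.fa"
    study.transcriptome.to_fasta(tx_path)
    paths["transcriptome"] = tx_path
    cfg_path = outdir / "config.json"
    cfg_path.write_text(json.dumps(asdict(study.config), indent=2))
    paths["config"] = cfg_path
    return paths
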