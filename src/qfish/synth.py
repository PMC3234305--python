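"""Ground-truthed synthetic MS/MS runs and spectral-count tables.

The generator emulates what the clustering pipeline exploits in real
Nano-LC-MS/MS data: each peptide has a fragment-peak template; replicated
acquisitions of that peptide are noisy copies (multiplicative lognormal
intensity noise, Bernoulli peak dropout, small Gaussian m/z and precursor
errors) eluting near a peptide-specific retention time; abundances differ
between the two sample groups with beta-binomial overdispersion.  Every
artifact comes with truth labels so recovery can be scored exactly.

The defaults mirror a triplicate two-group LC-MS/MS design (two samples,
three replicate runs each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dep import CountTable
from .signal import GridConfig, bin_spectrum, correlation_index, moving_average
from .spectra_io import RawSpectrum, SampleSheet, write_mgf

logger = logging.getLogger(__name__)

__all__ = ["PeptideTemplate", "SimConfig", "make_templates", "emit_spectra",
           "emit_counts", "write_run"]


class TemplateSeparationError(RuntimeError):
    """Could not draw templates satisfying the separation constraints."""


@dataclass
class PeptideTemplate:
    """Fragment-peak pattern, precursor m/z and elution time of one peptide."""

    template_id: str
    mz: np.ndarray                # fragment m/z, within the analysis grid
    intensity: np.ndarray         # relative intensities in (0, 1]
    precursor_mz: float
    elution_time: float           # seconds

    def __post_init__(self) -> None:
        if self.mz.size < 5:
            raise ValueError("a template needs at least 5 fragment peaks")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic runs.

    Noise scales are per-acquisition: ``intensity_noise_sd`` is the sd of
    lognormal multiplicative noise (log scale), ``mz_jitter_sd`` and
    ``precursor_sd`` are Gaussian errors in Da, ``rt_jitter_sd`` the
    Gaussian elution spread in seconds.  ``rate_per_replicate`` is the
    expected number of acquisitions of one peptide per run; true DEP
    templates have their rate scaled by ``dep_odds_ratio`` in the first
    group.
    """

    n_templates: int = 30
    groups: tuple[str, str] = ("HCC", "Normal")
    n_replicates: int = 3
    rate_per_replicate: float = 3.0
    n_peaks_range: tuple[int, int] = (10, 40)
    intensity_noise_sd: float = 0.3
    dropout_prob: float = 0.1
    mz_jitter_sd: float = 0.02
    precursor_sd: float = 0.1
    rt_jitter_sd: float = 30.0
    run_span: tuple[float, float] = (600.0, 6600.0)
    dep_fraction: float = 0.1
    dep_odds_ratio: float = 4.0
    # direct count sampling (emit_counts)
    pi_range: tuple[float, float] = (0.002, 0.02)
    phi: float = 0.05
    n_total_per_replicate: int = 5000
    # template separation; spacing None spreads precursors over 400-1600 Da
    # (never closer than 2 Da, i.e. 2x the clustering tolerance); an explicit
    # small spacing deliberately creates precursor collisions for stress tests
    separation_r: float = 0.3
    precursor_spacing: float | None = None
    collide_precursors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intensity_noise_sd", "mz_jitter_sd", "precursor_sd",
                     "rt_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be a probability")
        if not 0 <= self.dep_fraction <= 1:
            raise ValueError("dep_fraction must be a probability")


def make_templates(
    config: SimConfig,
    grid: GridConfig | None = None,
    max_attempts: int = 500,
) -> list[PeptideTemplate]:
    """Draw peptide templates that the pipeline can in principle separate.

    Fragment peaks are uniform over the grid range with relative
    intensities scaled to a maximum of 1; precursor m/z values are spaced
    at least ``precursor_spacing`` apart (unless a deliberate collision is
    requested, which places the first two templates within 1 Da); elution
    times are uniform over the run span.  Templates are rejection-sampled
    until all pairwise MWA correlations fall below ``separation_r``.
    """
    gcfg = grid or GridConfig()
    rng = np.random.default_rng(config.seed)
    margin = gcfg.bin_width * gcfg.window_k

    def draw_one(i: int, precursor: float) -> PeptideTemplate:
        n_peaks = int(rng.integers(*config.n_peaks_range, endpoint=True))
        mz = np.sort(rng.uniform(gcfg.mz_min + margin, gcfg.mz_max - margin, n_peaks))
        inten = rng.uniform(0.05, 1.0, n_peaks)
        inten /= inten.max()
        return PeptideTemplate(
            template_id=f"T{i}",
            mz=mz,
            intensity=inten,
            precursor_mz=precursor,
            elution_time=float(rng.uniform(*config.run_span)),
        )

    lo, hi = 400.0, 1600.0
    if config.precursor_spacing is None:
        step = max(2.0, (hi - lo) / max(config.n_templates, 1))
    else:
        step = config.precursor_spacing
    precursors = lo + np.arange(config.n_templates) * step
    if config.collide_precursors and config.n_templates >= 2:
        precursors[1] = precursors[0] + 0.4

    templates = [draw_one(i, float(p)) for i, p in enumerate(precursors)]
    profiles = [
        moving_average(bin_spectrum(t, gcfg)) for t in templates
    ]
    for _ in range(max_attempts):
        worst = None
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                r = correlation_index(profiles[i], profiles[j])
                if r >= config.separation_r and (worst is None or r > worst[0]):
                    worst = (r, i, j)
        if worst is None:
            return templates
        _, _, j = worst
        templates[j] = replace(
            draw_one(j, templates[j].precursor_mz),
            elution_time=templates[j].elution_time,
        )
        profiles[j] = moving_average(bin_spectrum(templates[j], gcfg))
    raise TemplateSeparationError(
        f"could not separate {config.n_templates} templates below "
        f"r={config.separation_r} in {max_attempts} attempts"
    )


def emit_spectra(
    templates: list[PeptideTemplate],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RawSpectrum], pd.DataFrame]:
    """Noisy replicated acquisitions of each template, with truth labels.

    Per template, group and replicate the number of acquisitions is
    Poisson with the group rate (DEP templates are ``dep_odds_ratio``
    times more abundant in the first group).  Returns the spectra and a
    truth frame (spectrum_id, template_id, sample, replicate, is_dep).
    Spectra that lose every peak to dropout are not emitted (the count is
    logged), mirroring what an instrument simply would not record.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_dep = int(round(config.dep_fraction * len(templates)))
    dep_ids = {t.template_id for t in templates[:n_dep]}
    spectra: list[RawSpectrum] = []
    truth_rows = []
    n_empty = 0
    for t in templates:
        for g_idx, group in enumerate(config.groups):
            rate = config.rate_per_replicate
            if t.template_id in dep_ids and g_idx == 0:
                rate *= config.dep_odds_ratio
            for rep in range(1, config.n_replicates + 1):
                for _ in range(rng.poisson(rate)):
                    keep = rng.random(t.mz.size) >= config.dropout_prob
                    if not keep.any():
                        n_empty += 1
                        continue
                    mz = t.mz[keep] + rng.normal(0, config.mz_jitter_sd, keep.sum())
                    inten = t.intensity[keep] * np.exp(
                        rng.normal(0, config.intensity_noise_sd, keep.sum())
                    )
                    order = np.argsort(mz)
                    sid = f"{t.template_id}.{group}.{rep}.{len(spectra)}"
                    spectra.append(
                        RawSpectrum(
                            spectrum_id=sid,
                            mz=mz[order],
                            intensity=inten[order],
                            precursor_mz=t.precursor_mz
                            + float(rng.normal(0, config.precursor_sd)),
                            retention_time=max(
                                0.0,
                                t.elution_time
                                + float(rng.normal(0, config.rt_jitter_sd)),
                            ),
                            sample=group,
                            replicate=str(rep),
                        )
                    )
                    truth_rows.append(
                        (sid, t.template_id, group, str(rep),
                         t.template_id in dep_ids)
                    )
    if n_empty:
        logger.info("dropout removed every peak of %d acquisition(s)", n_empty)
    truth = pd.DataFrame(
        truth_rows,
        columns=["spectrum_id", "template_id", "sample", "replicate", "is_dep"],
    )
    return spectra, truth


def emit_counts(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, np.ndarray]:
    """Sample a spectral-count table directly from the beta-binomial model.

    Each cluster gets a base proportion pi drawn from ``pi_range`` and the
    shared overdispersion ``phi``; true DEP clusters (the first
    ``dep_fraction`` of rows) have their odds multiplied by
    ``dep_odds_ratio`` in the first group.  Counts are beta-binomial:
    p ~ Beta(alpha, beta) per replicate, then x ~ Binomial(n, p).  Returns
    the table and the boolean truth vector of DEP rows.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n_rows = config.n_templates
    n_dep = int(round(config.dep_fraction * n_rows))
    is_dep = np.zeros(n_rows, dtype=bool)
    is_dep[:n_dep] = True
    keys = [
        (g, str(r))
        for g in config.groups
        for r in range(1, config.n_replicates + 1)
    ]
    n = np.full(len(keys), config.n_total_per_replicate)
    x = np.zeros((n_rows, len(keys)), dtype=int)
    phi = config.phi
    for i in range(n_rows):
        pi0 = rng.uniform(*config.pi_range)
        odds = pi0 / (1 - pi0)
        pi_first = (
            odds * config.dep_odds_ratio / (1 + odds * config.dep_odds_ratio)
            if is_dep[i]
            else pi0
        )
        for j, (g, _) in enumerate(keys):
            pi = pi_first if g == config.groups[0] else pi0
            if phi > 0:
                a = pi * (1 - phi) / phi
                b = (1 - pi) * (1 - phi) / phi
                p = rng.beta(a, b)
            else:
                p = pi
            x[i, j] = rng.binomial(n[j], p)
    table = CountTable(
        x=x,
        n=n,
        replicate_keys=keys,
        groups=[k[0] for k in keys],
        cluster_ids=[f"C{i}" for i in range(n_rows)],
        occupancy=["shared"] * n_rows,
    )
    return table, is_dep


def write_run(
    spectra: list[RawSpectrum],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> SampleSheet:
    """Write one MGF per (sample, replicate) run plus sample sheet and truth.

    Produces ``<sample>_<replicate>.mgf`` files, ``sample_sheet.tsv`` keyed
    by file name, and ``truth.tsv`` so downstream evaluation needs no
    hidden state.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_run: dict[tuple[str, str], list[RawSpectrum]] = {}
    for s in spectra:
        by_run.setdefault(s.replicate_key, []).append(s)
    rows = []
    for (sample, rep), run in sorted(by_run.items()):
        name = f"{sample}_{rep}.mgf"
        write_mgf(run, out / name)
        rows.append((name, sample, rep))
    sheet = SampleSheet(rows)
    sheet.write(out / "sample_sheet.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return sheet
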