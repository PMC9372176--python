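"""Synthetic peptide-array, module and serology data.

Every generator is a pure function of ``(config, seed)``.  The emulated
structure mirrors what the analysis stages assume about real arrays:

* background fluorescence is log-normal per peptide x sample — scanner
  signals are positive and right-skewed;
* a true epitope shows up as a run of >= 2 tiling-adjacent peptides whose
  intensity is multiplied by an effect size, in a subset of case samples
  only (antibody repertoires differ between patients, so not every case
  carries every epitope);
* co-expression modules are groups of peptides sharing a latent factor on
  the log scale, one of which drives a continuous pseudo-proteinuria trait;
* serology titers are log-normal around a group median.

Default study conditions follow the discovery design: 10 disease cases
versus 4 healthy controls, 16-mer peptides at stride 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import EpitopeTruth, IntensityMatrix, PlantedRun, SampleMetadata
from .library import AA_ALPHABET, PeptideLibrary


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with the study-design defaults.

    Epitope runs default to 3-6 peptides: with 16-mers at stride 3 a
    contiguous epitope plus partial-overlap binding reaches a handful of
    consecutive probes.  The multiplicative effect (default 100) represents
    a strongly seropositive signal over background.
    """

    seed: int = 0
    # proteome
    n_proteins: int = 100
    protein_length: tuple[int, int] = (80, 300)
    decoy_fraction: float = 0.0           # proteins carrying a homopolymer stretch
    decoy_run_length: int = 20
    # array design and cohort
    k: int = 16
    step: int = 3
    n_cases: int = 10
    n_controls: int = 4
    # background fluorescence, log scale
    background_meanlog: float = math.log(1000.0)
    background_sdlog: float = 0.6
    # planted epitopes
    n_epitopes: int = 3
    run_length: tuple[int, int] = (3, 6)
    effect_size: float = 100.0
    carrier_fraction: float = 0.7         # fraction of cases carrying each epitope
    # co-expression module structure
    n_modules: int = 3
    peptides_per_module: int = 40
    n_noise_peptides: int = 20
    n_module_samples: int = 50
    #: per-peptide loading on the module factor is drawn uniformly from this
    #: range — modules have hubs and peripheral members, as real
    #: co-expression networks do
    module_loading: tuple[float, float] = (0.6, 0.95)
    trait_rho: float = 0.8                # latent-factor / trait correlation
    trait_name: str = "proteinuria_T12"
    # serology: group -> (median RU/ml, log-sd, n subjects)
    serology_groups: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: {
            "healthy": (1.0, 0.5, 40),
            "MN": (4.0, 0.7, 60),
        }
    )

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_cases", "n_controls", "n_epitopes",
                     "n_modules", "peptides_per_module", "n_noise_peptides"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_epitopes and not self.effect_size > 1:
            raise ValueError("effect_size must be > 1")
        if self.run_length[0] < 2 or self.run_length[1] < self.run_length[0]:
            raise ValueError("run_length must be (lo, hi) with 2 <= lo <= hi")
        if not -1.0 <= self.trait_rho <= 1.0:
            raise ValueError("trait_rho must lie in [-1, 1]")
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in (0, 1]")
        lo, hi = self.module_loading
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("module_loading must be (lo, hi) within [0, 1]")


def generate_proteome(config: SimulationConfig) -> list[SeqRecord]:
    """Draw random proteins over the 20 standard amino acids.

    A ``decoy_fraction`` of proteins receives a deliberate homopolymer
    stretch (low sequence complexity) to exercise the entropy filter.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length
    records: list[SeqRecord] = []
    aa = np.array(list(AA_ALPHABET))
    for i in range(config.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=L))
        if config.decoy_fraction and rng.random() < config.decoy_fraction:
            run = config.decoy_run_length
            if L > run:
                pos = int(rng.integers(0, L - run))
                letter = str(rng.choice(aa))
                seq = seq[:pos] + letter * run + seq[pos + run :]
        records.append(SeqRecord(Seq(seq), id=f"PROT{i:05d}", description=""))
    return records


def _cohort_metadata(config: SimulationConfig) -> SampleMetadata:
    rows = []
    for i in range(config.n_cases):
        rows.append((f"MN{i:03d}", "MN", "NA", np.nan, np.nan, np.nan, "NA"))
    for i in range(config.n_controls):
        rows.append((f"HC{i:03d}", "healthy", "NA", np.nan, np.nan, np.nan, "NA"))
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "group", "anti_pla2r1",
            "proteinuria_T0", "proteinuria_T12", "proteinuria_T24", "outcome",
        ],
    )
    return SampleMetadata(df)


def simulate_array(
    library: PeptideLibrary, config: SimulationConfig
) -> tuple[IntensityMatrix, SampleMetadata, EpitopeTruth]:
    """Simulate one discovery array over ``library``.

    Background is i.i.d. log-normal; each planted epitope multiplies the
    intensities of its run peptides by ``effect_size`` in the carrier case
    samples only.  Returns the matrix, the cohort metadata and the ground
    truth of planted runs.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    rng = np.random.default_rng(config.seed)
    metadata = _cohort_metadata(config)
    n_pep, n_samp = len(library), len(metadata.sample_ids)
    values = rng.lognormal(
        config.background_meanlog, config.background_sdlog, size=(n_pep, n_samp)
    )

    truth = EpitopeTruth()
    if config.n_epitopes:
        block_len = library.block_lengths()
        block_start = np.r_[0, np.cumsum(block_len)[:-1]]
        case_cols = np.arange(config.n_cases)  # cases listed first
        prot = library.df["protein_id"].to_numpy()
        for _ in range(config.n_epitopes):
            N = int(rng.integers(config.run_length[0], config.run_length[1] + 1))
            eligible = np.flatnonzero(block_len >= N)
            if eligible.size == 0:
                raise ValueError(
                    f"no tiling chain long enough for a run of {N} peptides"
                )
            b = int(rng.choice(eligible))
            offset = int(rng.integers(0, block_len[b] - N + 1))
            start = int(block_start[b] + offset)
            n_carriers = max(1, round(config.carrier_fraction * config.n_cases))
            carriers = rng.choice(case_cols, size=n_carriers, replace=False)
            values[np.ix_(range(start, start + N), carriers)] *= config.effect_size
            truth.runs.append(
                PlantedRun(
                    protein_id=str(prot[start]),
                    start_index=start,
                    length=N,
                    sample_ids=[metadata.sample_ids[c] for c in sorted(carriers)],
                    effect=config.effect_size,
                )
            )
    matrix = IntensityMatrix(values, library.peptide_ids, metadata.sample_ids, library=library)
    return matrix, metadata, truth


@dataclass
class ModuleTruth:
    """Ground truth of the module simulation: per-peptide module labels
    (0 = noise) and the index of the trait-coupled module (label 1)."""

    labels: np.ndarray
    coupled_module: int = 1


def simulate_trait_coupled_modules(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, pd.DataFrame, ModuleTruth]:
    """Simulate peptides organised in co-expression modules plus a trait.

    Peptides of module *m* share a latent factor on the log-intensity scale
    with loading ``module_loading``; remaining variance is independent
    noise.  A continuous pseudo-proteinuria trait is a linear function of
    module 1's latent factor calibrated so its correlation with the factor
    is ``trait_rho``.  Noise peptides carry no shared factor.
    """
    if config.n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_mod, per_mod = config.n_modules, config.peptides_per_module
    n_samp = config.n_module_samples
    n_pep = n_mod * per_mod + config.n_noise_peptides

    factors = rng.standard_normal((n_mod, n_samp))
    logx = np.empty((n_pep, n_samp))
    labels = np.zeros(n_pep, dtype=int)
    row = 0
    for m in range(n_mod):
        load = rng.uniform(*config.module_loading, size=(per_mod, 1))
        eps = rng.standard_normal((per_mod, n_samp))
        logx[row : row + per_mod] = load * factors[m] + np.sqrt(1 - load**2) * eps
        labels[row : row + per_mod] = m + 1
        row += per_mod
    logx[row:] = rng.standard_normal((n_pep - row, n_samp))

    rho = config.trait_rho
    trait = rho * factors[0] + math.sqrt(1 - rho**2) * rng.standard_normal(n_samp)

    values = np.exp(config.background_meanlog + config.background_sdlog * logx)
    peptide_ids = [f"pep{i:05d}" for i in range(n_pep)]
    sample_ids = [f"S{j:03d}" for j in range(n_samp)]
    matrix = IntensityMatrix(values, peptide_ids, sample_ids)
    traits = pd.DataFrame({"sample_id": sample_ids, config.trait_name: trait})
    return matrix, traits, ModuleTruth(labels=labels, coupled_module=1)


def simulate_serology(config: SimulationConfig) -> pd.DataFrame:
    """Draw log-normal titers around each group's median.

    Returns a tidy table with columns ``subject, group, titer``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, (median, sdlog, n) in config.serology_groups.items():
        titers = median * np.exp(sdlog * rng.standard_normal(n))
        for i, t in enumerate(titers):
            rows.append((f"{group}_{i:03d}", group, float(t)))
    return pd.DataFrame(rows, columns=["subject", "group", "titer"])
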