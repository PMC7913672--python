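"""Synthetic partially-deaminated amplicon reads.

Generates read sets with the statistical structure of a nitrous-acid
deamination experiment, inverting the observed signal rules into a
generative model:

* unmethylated A converts to inosine with probability ``p_AtoI`` and then
  reads as G;
* C converts to uridine with probability ``p_CtoU`` and reads as T;
* G converts to xanthosine (X) more slowly (``p_GtoX``); X partially blocks
  reverse transcription (``p_X_block``) and, when read through, yields
  mostly G with a minor A signal (``p_X_reads_A``);
* m6A resists deamination (its exocyclic amine is methylated), so
  methylated molecules keep their A signal at the site; a configurable
  fraction may nevertheless behave as unmethylated (``p_m6A_deaminated``)
  or form the nitrosation product NOm6A (``p_NOm6A``), whose base-pairing
  is modelled as either reading A or blocking RT.

Site-to-site reactivity variance is modelled as a mean-preserving lognormal
multiplicative jitter on the A and C conversion rates, drawn once per
simulation run.  Without it the downstream z-statistic would resolve
arbitrarily small stoichiometries at high depth, which partial-deamination
data does not support.

Optional layers reproduce library artefacts: a 7-nt random UMI per
molecule, PCR duplication (duplicates share sequence and UMI), antibody
(MeRIP-style) enrichment of methylated molecules, and a uniform sequencing
error rate (default 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .align import BASES, encode
from .exceptions import ConfigurationError, ValidationError
from .io import ReferenceAmplicon, StructuredRead

__all__ = [
    "TEMPERATURES_C",
    "PH_VALUES",
    "TIMES_MIN",
    "DeaminationCondition",
    "ChemistryModel",
    "MeripModel",
    "SimulationParams",
    "condition_grid",
    "condition_preset",
    "simulate_reads",
    "demo_reference",
]

# The screening grid of the wet-lab protocol this simulator replaces.
TEMPERATURES_C = (50, 60, 70)
PH_VALUES = (3.5, 4.0, 4.5, 5.0)
TIMES_MIN = (1, 3, 5, 10, 20, 30)

# The synthetic 53-mer test oligo (RNA, written here in DNA alphabet) with
# m6A at position 33; positions 31-32 are G.
_53MER = "ATAGGGGAATGGGCCGTTCATCTGCTAAAAGGACTGCTTTTGGGGCTTGTAGT"


def demo_reference() -> ReferenceAmplicon:
    """The built-in 53-mer test amplicon with m6A annotated at position 33."""
    return ReferenceAmplicon(
        name="m6A_53mer", sequence=_53MER, modified_positions=(33,)
    )


@dataclass(frozen=True)
class DeaminationCondition:
    """One cell of the temperature x pH x time screening grid."""

    temperature: float  # deg C
    ph: float
    time: float  # minutes
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.temperature:g}C_pH{self.ph:g}_{self.time:g}min"
            )


def condition_grid() -> list[DeaminationCondition]:
    """The full 72-condition screening grid.

    Cartesian product of 3 temperatures, 4 pH values and 6 incubation
    times, ordered by ascending temperature, then pH, then time.
    """
    return [
        DeaminationCondition(t, ph, minutes)
        for t, ph, minutes in itertools.product(TEMPERATURES_C, PH_VALUES, TIMES_MIN)
    ]


@dataclass(frozen=True)
class ChemistryModel:
    """Per-base conversion probabilities of one deamination condition.

    Guanosine deamination is the slowest reaction, so presets keep
    ``p_GtoX`` below both ``p_AtoI`` and ``p_CtoU``.  ``nom6a_behavior``
    selects how NOm6A (base-pairing unknown) is modelled; ``nom6a_weight``
    is the probability that the selected behaviour applies (the remainder
    takes the other behaviour).
    """

    p_AtoI: float
    p_CtoU: float
    p_GtoX: float
    p_X_reads_A: float = 0.1
    p_X_block: float = 0.5
    p_m6A_deaminated: float = 0.0
    p_NOm6A: float = 0.0
    nom6a_behavior: str = "reads_A"
    nom6a_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "p_AtoI", "p_CtoU", "p_GtoX", "p_X_reads_A",
            "p_X_block", "p_m6A_deaminated", "p_NOm6A", "nom6a_weight",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
        if self.nom6a_behavior not in ("reads_A", "blocks_RT"):
            raise ValidationError(
                f"unknown nom6a_behavior {self.nom6a_behavior!r}"
            )


_PRESETS = {
    # Strong partial deamination of the synthetic oligo screening optimum:
    # A-to-I in the 10-50% working regime, C slightly faster, G far slower.
    "optimal_oligo": ChemistryModel(
        p_AtoI=0.30, p_CtoU=0.35, p_GtoX=0.03, p_X_block=0.5, p_NOm6A=0.10
    ),
    # Milder conditions used for targeted amplicons on biological RNA.
    "amplicon": ChemistryModel(
        p_AtoI=0.15, p_CtoU=0.20, p_GtoX=0.01, p_X_block=0.5, p_NOm6A=0.05
    ),
}


def condition_preset(name: str) -> ChemistryModel:
    """Named chemistry presets ('optimal_oligo' or 'amplicon')."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown condition preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class MeripModel:
    """Antibody enrichment of methylated molecules before sequencing."""

    enrichment_factor: float = 10.0
    background_retention: float = 1.0

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1.0:
            raise ValidationError("enrichment_factor must be >= 1")
        if not 0.0 <= self.background_retention <= 1.0:
            raise ValidationError("background_retention outside [0, 1]")


@dataclass
class SimulationParams:
    """Everything that defines one simulated library.

    ``n_reads`` is the number of sequenced reads emitted;
    ``pcr_duplication_rate`` is the expected fraction of them that are PCR
    copies of another molecule.  ``m6a_stoichiometry`` maps annotated
    modified positions to their per-molecule methylation probability.
    ``position_rate_jitter`` is the sigma of the lognormal site-reactivity
    jitter on the A and C conversion rates.
    """

    reference: ReferenceAmplicon
    m6a_stoichiometry: dict[int, float] = field(default_factory=dict)
    n_reads: int = 10_000
    pcr_duplication_rate: float = 0.0
    umi_length: int = 7
    position_rate_jitter: float = 0.15
    merip: MeripModel | None = None
    seq_error_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        annotated = set(self.reference.modified_positions)
        for pos, frac in self.m6a_stoichiometry.items():
            if pos not in annotated:
                raise ValidationError(
                    f"stoichiometry given for position {pos}, which is not an "
                    f"annotated modified position of {self.reference.name}"
                )
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"stoichiometry at {pos} outside [0, 1]")
        if self.n_reads < 1:
            raise ValidationError("n_reads must be >= 1")
        if not 0.0 <= self.pcr_duplication_rate < 1.0:
            raise ValidationError("pcr_duplication_rate outside [0, 1)")


def _jittered(rate: float, n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-preserving lognormal jitter, clipped to [0, 1]."""
    if sigma == 0.0 or rate == 0.0:
        return np.full(n, rate)
    draw = rate * np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma * sigma)
    return np.clip(draw, 0.0, 1.0)


def _random_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    ascii_map = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return [ascii_map[row].tobytes().decode() for row in codes]


def simulate_reads(
    params: SimulationParams, chem: ChemistryModel
) -> tuple[list[StructuredRead], pd.DataFrame]:
    """Generate one library and its per-molecule truth table.

    Per unique molecule: draw methylation states from the stoichiometry,
    (optionally) apply MeRIP retention by rejection sampling, draw per-base
    conversion events at position-jittered rates, truncate at the first
    RT-blocking xanthosine (the emitted 5' fragment later fails the
    coverage filter, reproducing survivor bias), read the converted bases
    out, and attach a random UMI.  PCR duplicates are exact copies of a
    molecule (same sequence and UMI) and replace the configured fraction of
    reads; sequencing errors (if any) are drawn per read afterwards.

    Returns ``(reads, truth)`` where ``truth`` has one row per read with
    molecule id, methylation state, converted positions and truncation.
    Byte-identical output for equal seeds.
    """
    rng = np.random.default_rng(params.seed)
    ref = params.reference
    length = len(ref)
    ref_codes = encode(ref.sequence)
    a_mask = ref_codes == 0
    c_mask = ref_codes == 1
    g_mask = ref_codes == 2
    site_idx = np.array([p - 1 for p in ref.modified_positions], dtype=int)
    site_stoich = np.array(
        [params.m6a_stoichiometry.get(p, 0.0) for p in ref.modified_positions]
    )
    # modified positions are handled by the site logic, not the bulk A logic
    bulk_a_mask = a_mask.copy()
    bulk_a_mask[site_idx] = False

    n_out = params.n_reads
    dup_flags = rng.random(n_out) < params.pcr_duplication_rate
    if dup_flags.all():  # need at least one template to copy
        dup_flags[0] = False
    n_fresh = int((~dup_flags).sum())

    # --- methylation states (with MeRIP rejection sampling if configured) ---
    if params.merip is None:
        meth = rng.random((n_fresh, len(site_idx))) < site_stoich[None, :]
    else:
        factor = params.merip.enrichment_factor
        background = params.merip.background_retention
        top = max(factor, background)
        if top == 0.0:
            raise ValidationError("MeRIP model retains no molecules at all")
        kept: list[np.ndarray] = []
        n_kept = 0
        while n_kept < n_fresh:
            batch = max(1024, 2 * (n_fresh - n_kept))
            states = rng.random((batch, len(site_idx))) < site_stoich[None, :]
            is_meth = states.any(axis=1) if len(site_idx) else np.zeros(batch, bool)
            weight = np.where(is_meth, factor, background) / top
            accept = rng.random(batch) < weight
            if not accept.any() and background == 0.0 and not is_meth.any():
                raise ValidationError(
                    "MeRIP with background_retention=0 but no methylated molecules"
                )
            kept.append(states[accept])
            n_kept += int(accept.sum())
        meth = np.concatenate(kept)[:n_fresh]

    # --- per-position conversion rates, jittered once per run ---
    rate = np.zeros(length)
    rate[bulk_a_mask] = _jittered(
        chem.p_AtoI, int(bulk_a_mask.sum()), params.position_rate_jitter, rng
    )
    rate[c_mask] = _jittered(
        chem.p_CtoU, int(c_mask.sum()), params.position_rate_jitter, rng
    )
    rate[g_mask] = chem.p_GtoX
    site_rates = _jittered(
        chem.p_AtoI, len(site_idx), params.position_rate_jitter, rng
    )

    # --- conversion events ---
    conv = rng.random((n_fresh, length)) < rate[None, :]
    if len(site_idx):
        behaves_unmeth = ~meth | (
            rng.random((n_fresh, len(site_idx))) < chem.p_m6A_deaminated
        )
        conv[:, site_idx] = behaves_unmeth & (
            rng.random((n_fresh, len(site_idx))) < site_rates[None, :]
        )
        nitrosated = meth & (rng.random((n_fresh, len(site_idx))) < chem.p_NOm6A)
        p_blocks = (
            1.0 - chem.nom6a_weight
            if chem.nom6a_behavior == "reads_A"
            else chem.nom6a_weight
        )
        nom6a_blocks = nitrosated & (
            rng.random((n_fresh, len(site_idx))) < p_blocks
        )
    else:
        nom6a_blocks = np.zeros((n_fresh, 0), dtype=bool)

    # --- RT truncation at xanthosine (and RT-blocking NOm6A) ---
    x_events = conv & g_mask[None, :]
    block_candidates = x_events & (rng.random((n_fresh, length)) < chem.p_X_block)
    if len(site_idx):
        block_candidates[:, site_idx] |= nom6a_blocks
    any_block = block_candidates.any(axis=1)
    first_block = np.where(any_block, block_candidates.argmax(axis=1), length)
    read_len_fresh = first_block  # emitted fragment: positions 1..first_block

    # --- readout ---
    out = np.tile(ref_codes, (n_fresh, 1))
    out[conv & bulk_a_mask[None, :]] = 2  # A -> I reads G
    out[conv & c_mask[None, :]] = 3  # C -> U reads T
    x_read_through = x_events
    reads_a = x_read_through & (rng.random((n_fresh, length)) < chem.p_X_reads_A)
    out[x_read_through] = 2  # X mostly reads G
    out[reads_a] = 0  # minor A signal at read-through X
    if len(site_idx):
        site_cols = out[:, site_idx]
        site_cols[conv[:, site_idx]] = 2  # deaminated site behaves like A->I
        out[:, site_idx] = site_cols  # methylated & intact stays A

    umis = _random_umis(n_fresh, params.umi_length, rng)

    # --- expand to the read stream (fresh + PCR duplicates) ---
    fresh_positions = np.nonzero(~dup_flags)[0]
    dup_positions = np.nonzero(dup_flags)[0]
    source = rng.integers(0, n_fresh, size=len(dup_positions))
    molecule_of = np.empty(n_out, dtype=int)
    molecule_of[fresh_positions] = np.arange(n_fresh)
    molecule_of[dup_positions] = source

    seq_matrix = out[molecule_of]
    if params.seq_error_rate > 0.0:
        err = rng.random((n_out, length)) < params.seq_error_rate
        shift = rng.integers(1, 4, size=(n_out, length), dtype=np.uint8)
        seq_matrix = np.where(err, (seq_matrix + shift) % 4, seq_matrix)
    lengths = read_len_fresh[molecule_of]

    ascii_map = np.frombuffer(BASES.encode(), dtype=np.uint8)
    ascii_matrix = ascii_map[seq_matrix]
    is_dup = dup_flags
    reads: list[StructuredRead] = []
    dup_serial = 0
    for i in range(n_out):
        mol = molecule_of[i]
        if is_dup[i]:
            dup_serial += 1
            read_id = f"mol{mol:06d}_dup{dup_serial}"
        else:
            read_id = f"mol{mol:06d}"
        n_bases = int(lengths[i])
        insert = ascii_matrix[i, :n_bases].tobytes().decode()
        reads.append(
            StructuredRead(
                read_id=read_id,
                insert=insert,
                umi=umis[mol] if params.umi_length else None,
                qualities="I" * n_bases,
            )
        )

    # --- truth table ---
    meth_strings = [
        ";".join(
            f"{p}:{int(meth[molecule_of[i], j])}"
            for j, p in enumerate(ref.modified_positions)
        )
        for i in range(n_out)
    ]
    conv_strings = [
        ",".join(str(j + 1) for j in np.nonzero(conv[molecule_of[i]])[0])
        for i in range(n_out)
    ]
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "molecule_id": [f"mol{m:06d}" for m in molecule_of],
            "is_duplicate": is_dup,
            "umi": [r.umi for r in reads],
            "methylation": meth_strings,
            "converted_positions": conv_strings,
            "truncated_at": [
                int(first_block[molecule_of[i]]) + 1 if any_block[molecule_of[i]] else 0
                for i in range(n_out)
            ],
        }
    )
    return reads, truth
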