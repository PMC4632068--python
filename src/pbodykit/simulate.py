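"""Synthetic data generators with known ground truth for every pipeline stage.

The defaults encode the study design being emulated: five bait
immunopurifications (three from glucose-depleted cultures, two from
glucose-replete), ten negative-control purifications, an I-DIRT mixing
experiment with a 1:1 light:heavy lysate mix, a custom two-channel probe
array with three 60-bp probes per transcript and 1559 negative-control
features, and a mock (tag-only) IP.  Every generator is driven by a single
integer seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "InvalidConfigError",
    "SimulationConfig",
    "GroundTruth",
    "simulate_apms",
    "simulate_idirt",
    "simulate_array",
    "simulate_sequences",
]

MINUS, PLUS = "minus_glucose", "plus_glucose"

# Approximate S. cerevisiae proteome residue frequencies.
YEAST_AA_FREQS = {
    "A": 0.055, "C": 0.013, "D": 0.058, "E": 0.065, "F": 0.045,
    "G": 0.050, "H": 0.022, "I": 0.066, "K": 0.073, "L": 0.096,
    "M": 0.021, "N": 0.061, "P": 0.044, "Q": 0.039, "R": 0.044,
    "S": 0.090, "T": 0.059, "V": 0.056, "W": 0.010, "Y": 0.034,
}


class InvalidConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """All simulator knobs; defaults are the emulated study conditions."""

    seed: int = 0
    # --- AP-MS ---
    n_proteins: int = 300
    n_true_interactors: int = 30
    n_condition_specific: dict = field(
        default_factory=lambda: {MINUS: 16, PLUS: 6}
    )
    n_bait_replicates: dict = field(default_factory=lambda: {MINUS: 3, PLUS: 2})
    n_control_runs: int = 10
    contaminant_rate: float = 5.0
    enrichment_fold: float = 4.0
    depth: int = 5000
    bait_boost: float = 50.0  # bait mean count as multiple of contaminant_rate
    noise_model: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.5  # gamma shape heterogeneity for the NB option
    peptide_rate: float = 0.25  # unique peptides per spectral count
    # --- I-DIRT ---
    idirt_exchange_fraction: dict = field(
        default_factory=lambda: {"in_vivo": 0.2, "exchange": 1.0}
    )
    n_idirt_proteins: dict = field(
        default_factory=lambda: {"in_vivo": 40, "exchange": 20}
    )
    peptides_per_protein: int = 5
    idirt_noise_sd: float = 0.05  # SD of per-channel log-intensity noise
    # --- array ---
    n_transcripts: int = 1000
    n_spiked: int = 50
    spike_log2fc: float = 2.0
    array_noise_sd: float = 0.2
    n_neg_probes: int = 1559
    probes_per_transcript: int = 3
    n_array_replicates: int = 3
    capture_slope: float = 1.0
    capture_intercept: float = 0.0
    array_bg_level: float = 100.0
    n_saturated: int = 0
    saturation_value: float = 2**16 - 1
    # --- sequences ---
    seq_count: int = 100
    seq_length: int = 400
    lc_insert_length: int = 40
    n_lc_sequences: int = 20
    seq_composition: str = "yeast"  # or "uniform"

    def validate(self) -> None:
        n_special = 1 + self.n_true_interactors + sum(self.n_condition_specific.values())
        if n_special > self.n_proteins:
            raise InvalidConfigError(
                f"bait + interactors + condition-specific ({n_special}) exceeds "
                f"n_proteins ({self.n_proteins})"
            )
        for name, v in (
            ("n_proteins", self.n_proteins),
            ("n_true_interactors", self.n_true_interactors),
            ("n_control_runs", self.n_control_runs),
            ("depth", self.depth),
            ("n_transcripts", self.n_transcripts),
            ("n_spiked", self.n_spiked),
            ("seq_count", self.seq_count),
            ("seq_length", self.seq_length),
        ):
            if v < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if self.lc_insert_length < 0:
            raise InvalidConfigError("lc_insert_length must be nonnegative")
        for cls, e in self.idirt_exchange_fraction.items():
            if not 0.0 <= e <= 1.0:
                raise InvalidConfigError(f"exchange fraction for {cls!r} outside [0, 1]")
        if self.n_spiked > self.n_transcripts:
            raise InvalidConfigError("n_spiked exceeds n_transcripts")
        if self.probes_per_transcript < 1:
            raise InvalidConfigError("probes_per_transcript must be >= 1")
        if self.noise_model not in ("poisson", "nb"):
            raise InvalidConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.seq_composition not in ("yeast", "uniform"):
            raise InvalidConfigError(f"unknown seq_composition {self.seq_composition!r}")


@dataclass
class GroundTruth:
    """Which simulated ids carry which designed signal."""

    bait_id: str | None = None
    interactor_ids: list = field(default_factory=list)
    condition_specific_ids: dict = field(default_factory=dict)
    contaminant_ids: list = field(default_factory=list)
    in_vivo_ids: list = field(default_factory=list)
    exchange_ids: list = field(default_factory=list)
    spiked_transcript_ids: list = field(default_factory=list)
    saturated_transcript_ids: list = field(default_factory=list)
    lc_segments: dict = field(default_factory=dict)  # seq_id -> (start, end) 1-based

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_counts(rng: np.random.Generator, rates: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(rates)
    # negative binomial as a gamma-Poisson mixture with shape 1/dispersion
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, rates / shape)
    return rng.poisson(lam)


def simulate_apms(config: SimulationConfig):
    """Spectral-count tables for bait runs and controls, with ground truth.

    Every protein has a baseline bead-binding rate (gamma around
    ``contaminant_rate``) present in controls and bait runs alike; shared
    interactors are multiplied by ``enrichment_fold`` in all bait runs,
    condition-specific interactors only in their condition, and the bait
    carries the largest rate in bait runs (and none in controls, which come
    from untagged strains).  Rates are rescaled so each run's expected total
    equals ``depth`` before count noise is applied.

    Returns ``(counts, controls, observability, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = [f"P{i:04d}" for i in range(1, config.n_proteins + 1)]
    bait_id = ids[0]
    cursor = 1
    interactors = ids[cursor : cursor + config.n_true_interactors]
    cursor += config.n_true_interactors
    cond_specific: dict[str, list[str]] = {}
    for cond, n in config.n_condition_specific.items():
        cond_specific[cond] = ids[cursor : cursor + n]
        cursor += n
    contaminants = ids[cursor:]

    # Homogeneous baseline bead-binding rate; run-level variability comes from
    # the count-noise model (Poisson, or gamma-Poisson via noise_model="nb").
    base = pd.Series(float(config.contaminant_rate), index=ids)

    def bait_run_rates(condition: str) -> np.ndarray:
        r = base.copy()
        r[bait_id] = config.bait_boost * config.contaminant_rate
        r[interactors] *= config.enrichment_fold
        for cond, members in cond_specific.items():
            if cond == condition:
                r[members] *= config.enrichment_fold
        return r.to_numpy()

    rows = []
    for cond, n_rep in config.n_bait_replicates.items():
        rates = bait_run_rates(cond)
        rates = rates / rates.sum() * config.depth
        for rep in range(1, n_rep + 1):
            run = f"{'minus' if cond == MINUS else 'plus'}_rep{rep}"
            n = _draw_counts(rng, rates, config)
            u = np.minimum(n, np.maximum(rng.binomial(n, config.peptide_rate), (n > 0).astype(int)))
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": ids,
                        "run_id": run,
                        "condition": cond,
                        "spectral_count": n,
                        "unique_peptides": u,
                    }
                )
            )
    counts = pd.concat(rows, ignore_index=True)

    ctl_rates = base.copy()
    ctl_rates[bait_id] = 0.0  # untagged control strains carry no bait
    ctl_rates = ctl_rates.to_numpy()
    ctl_rates = ctl_rates / ctl_rates.sum() * config.depth
    ctl_rows = []
    for c in range(1, config.n_control_runs + 1):
        n = _draw_counts(rng, ctl_rates, config)
        ctl_rows.append(
            pd.DataFrame({"protein_id": ids, "control_run_id": f"control_{c:02d}", "count": n})
        )
    controls = pd.concat(ctl_rows, ignore_index=True)

    obs = pd.DataFrame(
        {
            "protein_id": ids,
            # log-uniform on [0.1, 1]: APEX needs strictly positive scores
            "observability": np.exp(rng.uniform(np.log(0.1), 0.0, size=config.n_proteins)),
        }
    )
    truth = GroundTruth(
        bait_id=bait_id,
        interactor_ids=list(interactors),
        condition_specific_ids={k: list(v) for k, v in cond_specific.items()},
        contaminant_ids=list(contaminants),
    )
    return counts, controls, obs, truth


def simulate_idirt(config: SimulationConfig):
    """Peptide-level light/heavy precursor areas under the 1:1 mixing model.

    A protein class with post-lysis exchange fraction ``e`` has expected
    light fraction ``phi = 1 - 0.5 e`` (e=0: bound in vivo, light only;
    e=1: fully equilibrated with the 1:1 mix, 50:50).  Each peptide draws a
    log-normal total precursor intensity split phi : 1-phi between channels,
    each channel perturbed by independent log-scale noise of SD
    ``idirt_noise_sd``.

    Returns ``(peptides, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    truth = GroundTruth()
    for cls, n_prot in config.n_idirt_proteins.items():
        e = config.idirt_exchange_fraction[cls]
        phi = 1.0 - 0.5 * e
        for i in range(1, n_prot + 1):
            pid = f"{cls.upper()}_{i:03d}"
            getattr(truth, "in_vivo_ids" if cls == "in_vivo" else "exchange_ids").append(pid)
            for j in range(1, config.peptides_per_protein + 1):
                total = float(np.exp(rng.normal(np.log(1e6), 1.0)))
                a_l = total * phi * float(np.exp(rng.normal(0.0, config.idirt_noise_sd)))
                a_h = total * (1.0 - phi) * float(np.exp(rng.normal(0.0, config.idirt_noise_sd)))
                rows.append(
                    {
                        "peptide_id": f"{pid}_pep{j}",
                        "protein_id": pid,
                        "light_area": a_l,
                        "heavy_area": a_h,
                        "elution_span_s": float(rng.uniform(6.0, 60.0)),
                        "mz_tol": 0.05,
                    }
                )
    return pd.DataFrame(rows), truth


def _array_probe_table(
    rng: np.random.Generator,
    config: SimulationConfig,
    transcript_log2: np.ndarray,
    probe_offsets: np.ndarray,
    spike: np.ndarray,
    transcripts: list[str],
) -> pd.DataFrame:
    """One paired (total, IP) probe table for a single hybridization pair."""
    k = config.probes_per_transcript
    n = len(transcripts)
    rep_effect = float(rng.normal(0.0, 0.1))
    base = np.repeat(transcript_log2, k) + probe_offsets + rep_effect
    log_total = base + rng.normal(0.0, config.array_noise_sd, size=n * k)
    log_ip = (
        config.capture_intercept
        + config.capture_slope * base
        + np.repeat(spike, k)
        + rng.normal(0.0, config.array_noise_sd, size=n * k)
    )
    bg_total = rng.normal(config.array_bg_level, 0.1 * config.array_bg_level, size=n * k)
    bg_ip = rng.normal(config.array_bg_level, 0.1 * config.array_bg_level, size=n * k)
    df = pd.DataFrame(
        {
            "probe_id": [f"{t}_p{j + 1}" for t in transcripts for j in range(k)],
            "transcript_id": np.repeat(transcripts, k),
            "is_negative_control": False,
            "raw_total": np.maximum(2.0**log_total + bg_total, 0.0),
            "raw_ip": np.maximum(2.0**log_ip + bg_ip, 0.0),
        }
    )
    neg = pd.DataFrame(
        {
            "probe_id": [f"NEG_{j:05d}" for j in range(1, config.n_neg_probes + 1)],
            "transcript_id": pd.Series([pd.NA] * config.n_neg_probes, dtype="object"),
            "is_negative_control": True,
            "raw_total": np.maximum(
                rng.normal(config.array_bg_level, 0.1 * config.array_bg_level, config.n_neg_probes), 0.0
            ),
            "raw_ip": np.maximum(
                rng.normal(config.array_bg_level, 0.1 * config.array_bg_level, config.n_neg_probes), 0.0
            ),
        }
    )
    return pd.concat([df, neg], ignore_index=True)


def simulate_array(config: SimulationConfig):
    """Paired IP/total probe arrays for each replicate plus a mock pair.

    Transcript log2 abundances are normal (mean 8, SD 1.5); IP signal tracks
    total through the capture line plus ``spike_log2fc`` for the spiked set;
    the mock IP carries no spikes.  Raw intensities are exponentiated log
    signals plus additive scanner background; negative-control probes carry
    background only.  Optionally ``n_saturated`` transcripts are pinned at
    the scanner ceiling on the total channel.

    Returns ``(replicates, mock, truth)`` where ``replicates`` maps
    ``rep1..repN`` to probe tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts = [f"T{i:05d}" for i in range(1, config.n_transcripts + 1)]
    spiked = transcripts[: config.n_spiked]
    saturated = transcripts[config.n_spiked : config.n_spiked + config.n_saturated]
    transcript_log2 = rng.normal(8.0, 1.5, size=config.n_transcripts)
    probe_offsets = rng.normal(
        0.0, 0.3, size=config.n_transcripts * config.probes_per_transcript
    )
    spike = np.zeros(config.n_transcripts)
    spike[: config.n_spiked] = config.spike_log2fc

    replicates = {}
    for r in range(1, config.n_array_replicates + 1):
        tbl = _array_probe_table(rng, config, transcript_log2, probe_offsets, spike, transcripts)
        if saturated:
            tbl.loc[tbl["transcript_id"].isin(saturated), "raw_total"] = config.saturation_value
        replicates[f"rep{r}"] = tbl
    mock = _array_probe_table(
        rng, config, transcript_log2, probe_offsets, np.zeros(config.n_transcripts), transcripts
    )
    if saturated:
        mock.loc[mock["transcript_id"].isin(saturated), "raw_total"] = config.saturation_value
    truth = GroundTruth(
        spiked_transcript_ids=list(spiked),
        saturated_transcript_ids=list(saturated),
    )
    return replicates, mock, truth


def simulate_sequences(config: SimulationConfig):
    """Protein sequences, a subset carrying an embedded low-complexity insert.

    Background residues are drawn from a yeast-like (or uniform) composition;
    the first ``n_lc_sequences`` sequences receive a homopolymer or Q/N
    dipeptide repeat of ``lc_insert_length`` residues at a recorded position
    (1-based inclusive coordinates in the ground truth).

    Returns ``(sequences, truth)`` with ``sequences`` an id -> string dict.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.seq_composition == "yeast":
        letters = np.array(list(YEAST_AA_FREQS))
        probs = np.array(list(YEAST_AA_FREQS.values()))
        probs = probs / probs.sum()
    else:
        letters = np.array(sorted(YEAST_AA_FREQS))
        probs = np.full(len(letters), 1.0 / len(letters))
    sequences: dict[str, str] = {}
    truth = GroundTruth()
    n_lc = min(config.n_lc_sequences, config.seq_count) if config.lc_insert_length > 0 else 0
    for i in range(1, config.seq_count + 1):
        sid = f"SEQ{i:04d}"
        seq = "".join(rng.choice(letters, size=config.seq_length, p=probs))
        if i <= n_lc:
            ins_len = config.lc_insert_length
            if rng.random() < 0.5:
                insert = "Q" * ins_len
            else:
                insert = ("QN" * ins_len)[:ins_len]
            margin = 20
            hi = max(margin + 1, config.seq_length - ins_len - margin)
            pos = int(rng.integers(margin, hi))  # 0-based insert start
            seq = seq[:pos] + insert + seq[pos + ins_len :]
            seq = seq[: config.seq_length]
            truth.lc_segments[sid] = (pos + 1, pos + ins_len)
        sequences[sid] = seq
    return sequences, truth
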