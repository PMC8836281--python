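"""Ground-truthed synthetic inputs: identification reports and assay plates.

The report generator emulates the statistical shape of the reference VOO
identification tables: observed masses perturbed by a normal ppm error,
m/z at charge 2–3, per-residue local confidences from a scaled Beta (giving
ALC in the low-to-mid 90s), log-normal label-free areas, and optional decoy
rows each constructed to violate exactly one acceptance rule (score, charge,
or sample replication).  The manifest returned alongside the rows records
which rows must survive default filtering, making filter recall and decoy
rejection exactly checkable.

The plate generator produces ACE-assay fluorescence readings from a
four-parameter logistic dose–response with known IC50 and Hill slope, and
ABTS responses with a known Trolox-equivalent ratio, both under
multiplicative noise.  All generators are seeded; there is no global random
state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assays import AssayPlate, TroloxCalibration
from .peptide import PROTON_MASS, Peptide, monoisotopic_mass
from .reports import PeptideRecord, compute_alc, records_to_frame

__all__ = [
    "ReportSimConfig",
    "AssaySimConfig",
    "four_pl_inhibition",
    "simulate_report",
    "simulate_plate",
    "simulate_abts",
    "write_simulated_report",
]

_VIOLATIONS = ("score", "charge", "replication")


@dataclass(frozen=True)
class ReportSimConfig:
    """Parameters of the synthetic identification report.

    Defaults emulate the reference tables: ppm_sigma 5 (printed |ppm| spans
    0.5–9.6), Beta(60, 4)-shaped per-residue confidences giving ALC ≈ 90–97,
    log-normal areas spanning ~1e4–1e7.
    """

    true_peptides: Tuple[str, ...] = ()  # empty -> the 27 reference sequences
    flavour: str = "db"
    n_samples: int = 2
    ppm_sigma: float = 5.0
    alc_beta_params: Tuple[float, float] = (60.0, 4.0)
    area_lognormal_params: Tuple[float, float] = (13.0, 1.5)
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flavour not in ("db", "denovo"):
            raise ValueError("flavour must be 'db' or 'denovo'")
        if self.ppm_sigma <= 0 or min(self.alc_beta_params) <= 0 \
                or self.area_lognormal_params[1] <= 0:
            raise ValueError("dispersion parameters must be positive")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def resolved_peptides(self) -> Tuple[str, ...]:
        if self.true_peptides:
            return tuple(self.true_peptides)
        from .datasets import voo_sequences

        return tuple(voo_sequences())


def _draw_confidences(rng: np.random.Generator, n: int, beta: Tuple[float, float],
                      min_alc: float, below: bool = False) -> Tuple[float, ...]:
    """Per-residue confidences with ALC guaranteed above (or below) threshold.

    Rejection sampling from the seeded stream keeps the construction
    deterministic while guaranteeing the manifest contract.
    """
    a, b = beta
    if below:
        # decoy rows: shift the confidence distribution down so sub-threshold
        # ALC values are typical rather than extreme-tail events
        a, b = a * 0.5, b * 2.5
    for _ in range(10000):
        conf = tuple(np.floor(rng.beta(a, b, size=n) * 100).clip(0, 99))
        alc = compute_alc(conf).mean
        if (alc < min_alc) == below and alc != min_alc:
            return tuple(float(c) for c in conf)
    raise RuntimeError("confidence sampling failed to satisfy the ALC bound")


def _random_sequence(rng: np.random.Generator, taken: set) -> str:
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(10000):
        n = int(rng.integers(7, 17))
        seq = "".join(rng.choice(residues, size=n))
        if seq not in taken:
            taken.add(seq)
            return seq
    raise RuntimeError("could not draw a fresh decoy sequence")


def _make_record(rng: np.random.Generator, seq: str, sample: str, flavour: str,
                 cfg: ReportSimConfig, *, z: Optional[int] = None,
                 score_below: bool = False) -> PeptideRecord:
    p = Peptide(seq)
    theo_mass = monoisotopic_mass(p)
    eps = rng.normal(0.0, cfg.ppm_sigma * 1e-6)
    obs_mass = theo_mass * (1.0 + eps)
    z = int(z if z is not None else rng.choice([2, 3]))
    obs_mz = (obs_mass + z * PROTON_MASS) / z
    mu, sigma = cfg.area_lognormal_params
    kwargs: dict = dict(
        peptide=p,
        observed_mz=obs_mz,
        observed_mass=obs_mass,
        z=z,
        sample_id=sample,
        rt=float(rng.uniform(10, 50)),
        ppm=eps * 1e6,
        area=float(rng.lognormal(mu, sigma)),
        accessions=("SIM0001",),
    )
    if flavour == "db":
        kwargs["neg10lgP"] = float(rng.uniform(5, 29.5) if score_below
                                   else rng.uniform(31, 95))
    else:
        conf = _draw_confidences(rng, len(p), cfg.alc_beta_params,
                                 min_alc=90.0, below=score_below)
        kwargs["local_confidence"] = conf
        kwargs["alc_percent"] = compute_alc(conf).mean
    return PeptideRecord(**kwargs)


def simulate_report(cfg: ReportSimConfig) -> Tuple[List[PeptideRecord], Dict]:
    """Generate report rows plus a ground-truth manifest.

    True rows are constructed to pass every default filter (score above
    threshold, z ∈ {2, 3}, present in every sample).  Each decoy violates
    exactly one rule — sub-threshold score, charge +1, or presence in a
    single sample — cycling through the three violation types.  The manifest
    lists, by row index, which rows must survive default filtering and which
    must not (with the violated rule).
    """
    rng = np.random.default_rng(cfg.seed)
    peptides = cfg.resolved_peptides()
    records: List[PeptideRecord] = []
    must_survive: List[int] = []
    decoys: Dict[int, str] = {}

    samples = [f"s{i + 1}" for i in range(cfg.n_samples)]
    for seq in peptides:
        for sample in samples:
            must_survive.append(len(records))
            records.append(_make_record(rng, seq, sample, cfg.flavour, cfg))

    n_true_rows = len(records)
    n_decoys = int(round(cfg.decoy_fraction / (1 - cfg.decoy_fraction) * n_true_rows)) \
        if cfg.decoy_fraction else 0
    taken = set(peptides)
    for k in range(n_decoys):
        violation = _VIOLATIONS[k % len(_VIOLATIONS)]
        seq = _random_sequence(rng, taken)
        if violation == "replication":
            rows = [_make_record(rng, seq, samples[0], cfg.flavour, cfg)]
        elif violation == "charge":
            rows = [_make_record(rng, seq, s, cfg.flavour, cfg, z=1) for s in samples]
        else:
            rows = [_make_record(rng, seq, s, cfg.flavour, cfg, score_below=True)
                    for s in samples]
        for row in rows:
            decoys[len(records)] = violation
            records.append(row)

    manifest = {
        "flavour": cfg.flavour,
        "n_true_peptides": len(peptides),
        "true_sequences": list(peptides),
        "must_survive": must_survive,
        "decoy_rows": {str(i): v for i, v in decoys.items()},
        "seed": cfg.seed,
    }
    return records, manifest


def write_simulated_report(records: Sequence[PeptideRecord], manifest: Dict,
                           report_path, manifest_path) -> None:
    """Write the rows as a delimited report and the manifest as JSON."""
    records_to_frame(records).to_csv(report_path, sep="\t", index=False)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)


# -- assay simulation -------------------------------------------------------

@dataclass(frozen=True)
class AssaySimConfig:
    """Ground truth for simulated ACE plates and ABTS runs."""

    true_ic50: float = 3.76
    hill: float = 1.0
    noise_cv: float = 0.02
    concentrations: Tuple[float, ...] = ()  # empty -> 7 points over ±1 decade
    true_teac: float = 3.20
    trolox_slope: float = 0.7
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def resolved_concentrations(self) -> Tuple[float, ...]:
        if self.concentrations:
            return tuple(self.concentrations)
        return tuple(np.geomspace(self.true_ic50 / 10, self.true_ic50 * 10, 7))


def four_pl_inhibition(conc: float, ic50: float, hill: float = 1.0) -> float:
    """Four-parameter logistic %, floor 0 / ceiling 100: 50 % at conc = IC50."""
    if conc <= 0:
        return 0.0
    return 100.0 / (1.0 + (ic50 / conc) ** hill)


def simulate_plate(cfg: AssaySimConfig, fc: float = 1000.0, fb: float = 100.0
                   ) -> AssayPlate:
    """ACE-assay plate whose noiseless readings invert to the true curve.

    Sample fluorescence is FS = FB + (FC − FB)(1 − inh/100) with
    multiplicative noise of coefficient ``noise_cv`` on each replicate
    reading; FBs is fixed at FB.
    """
    rng = np.random.default_rng(cfg.seed)
    readings = []
    for conc in cfg.resolved_concentrations():
        inh = four_pl_inhibition(conc, cfg.true_ic50, cfg.hill)
        fs_clean = fb + (fc - fb) * (1.0 - inh / 100.0)
        for _ in range(cfg.replicates):
            noise = rng.normal(1.0, cfg.noise_cv) if cfg.noise_cv else 1.0
            readings.append((float(conc), float(fs_clean * noise), fb))
    return AssayPlate(fc=fc, fb=fb, readings=tuple(readings))


def simulate_abts(
    cfg: AssaySimConfig,
    trolox_mM: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    sample_mM: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
) -> Tuple[TroloxCalibration, List[Tuple[float, float]]]:
    """Trolox calibration plus sample points with slope ratio ``true_teac``."""
    rng = np.random.default_rng(cfg.seed + 1)

    def noisy(x: float) -> float:
        return float(x * rng.normal(1.0, cfg.noise_cv)) if cfg.noise_cv else float(x)

    cal_points = []
    for c in trolox_mM:
        for _ in range(cfg.replicates):
            cal_points.append((float(c), noisy(cfg.trolox_slope * c)))
    sample_points = []
    for c in sample_mM:
        for _ in range(cfg.replicates):
            sample_points.append((float(c), noisy(cfg.trolox_slope * cfg.true_teac * c)))
    return TroloxCalibration(tuple(cal_points)), sample_points
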