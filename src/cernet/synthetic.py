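"""Synthetic tri-layer transcriptome generator with planted ground truth.

Emulates the study design the pipeline targets: two groups (control vs
treated) of 3 replicates each, with circRNA, miRNA and mRNA count layers.
The generator plants

* differentially expressed features at a known log2 fold change,
* ceRNA triplets (circRNA, miRNA, mRNA) whose members share a per-sample
  log-normal latent factor — positive for the circRNA and mRNA, negative
  for the miRNA — so the sponge sign pattern holds across samples,
* 8mer miRNA binding sites (with 3'-supplementary pairing) in the circRNA
  and mRNA sequences of each planted pair, and
* gene sets preferentially composed of DE mRNAs.

Counts are log-normal–Poisson with first two moments matched to a negative
binomial with dispersion ``nb_dispersion``; the log-normal mixing component
is what the cross-layer coupling shares, so coupling redistributes — rather
than inflates — within-group variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError
from .io_formats import CountMatrix, GeneSetCollection

LN2 = np.log(2.0)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the reference study design."""

    n_circ: int = 200
    n_mirna: int = 150
    n_mrna: int = 600
    n_per_group: int = 3
    nb_mean_log_range: tuple[float, float] = (1.5, 3.5)  # log10 mean counts
    mirna_mean_log_shift: float = 0.5  # miRNA libraries run deeper per feature
    nb_dispersion: float = 0.02
    n_de_per_class: dict[str, int] = field(
        default_factory=lambda: {"circRNA": 30, "miRNA": 20, "mRNA": 40}
    )
    de_log2fc_magnitude: float = 2.0
    n_planted_triplets: int = 10
    coupling_strength: float = 0.9
    n_support_mirnas: int = 2  # extra shared MREs per triplet (sequence level)
    seed_len: int = 7
    utr_len: int = 300
    sample_scale_sd: float = 0.15  # per-sample library size factor, log-normal
    n_background_terms: int = 40
    n_planted_terms: int = 5
    rng_seed: int = 1

    def validate(self) -> None:
        for name in ("n_circ", "n_mirna", "n_mrna", "n_per_group"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        lo, hi = self.nb_mean_log_range
        if not lo < hi:
            raise ConfigurationError("nb_mean_log_range must be an increasing interval")
        counts = {"circRNA": self.n_circ, "miRNA": self.n_mirna, "mRNA": self.n_mrna}
        for cls, n_de in self.n_de_per_class.items():
            if cls not in counts:
                raise ConfigurationError(f"n_de_per_class has unknown class {cls!r}")
            if n_de < 0 or n_de > counts[cls]:
                raise ConfigurationError(f"n_de_per_class[{cls!r}] out of range")
        if self.de_log2fc_magnitude < 0:
            raise ConfigurationError("de_log2fc_magnitude must be non-negative")
        if self.n_planted_triplets < 0 or self.n_planted_triplets > min(
            self.n_circ, self.n_mirna, self.n_mrna
        ):
            raise ConfigurationError(
                "n_planted_triplets must be <= min(n_circ, n_mirna, n_mrna)"
            )
        for cls in ("circRNA", "miRNA", "mRNA"):
            if self.n_planted_triplets > self.n_de_per_class.get(cls, 0) and (
                self.n_planted_triplets > 0
            ):
                raise ConfigurationError(
                    f"n_planted_triplets exceeds n_de_per_class[{cls!r}]"
                )
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ConfigurationError("coupling_strength must lie in [0, 1]")
        if self.seed_len != 7:
            raise ConfigurationError("seed_len must be 7 (miRNA positions 2-8)")
        if self.utr_len < 30:
            raise ConfigurationError("utr_len must be >= 30")
        if self.n_support_mirnas < 0:
            raise ConfigurationError("n_support_mirnas must be non-negative")


@dataclass
class PlantedTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    de_features: dict[str, list[tuple[str, int]]]  # class -> [(feature id, sign)]
    triplets: list[tuple[str, str, str]]  # (circ, mirna, mrna)
    enriched_terms: list[str] = field(default_factory=list)
    site_positions: list[tuple[str, str, int]] = field(default_factory=list)

    def de_ids(self, rna_class: str) -> list[str]:
        return [fid for fid, _ in self.de_features[rna_class]]


def feature_names(config: SimulationConfig) -> dict[str, list[str]]:
    """Deterministic feature identifiers per class."""
    return {
        "circRNA": [f"circ_{i:04d}" for i in range(config.n_circ)],
        "miRNA": [f"mir_{i:04d}" for i in range(config.n_mirna)],
        "mRNA": [f"mrna_{i:04d}" for i in range(config.n_mrna)],
    }


def _sigma_nat(dispersion: float) -> float:
    # log-normal sd (natural log) matching NB extra-Poisson variance
    return float(np.sqrt(np.log1p(dispersion)))


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, CountMatrix, PlantedTruth]:
    """Draw the three count layers and return them with the planted truth.

    Planted DE features have treated/control mean ratio 2**±de_log2fc_magnitude.
    Triplet members additionally share a per-sample latent factor scaled by
    ``coupling_strength`` (added to circRNA/mRNA log-means, subtracted from
    the miRNA log-mean). Identical config ⇒ identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    names = feature_names(config)
    n_s = 2 * config.n_per_group
    sample_ids = [f"ctrl_{i + 1}" for i in range(config.n_per_group)] + [
        f"nic_{i + 1}" for i in range(config.n_per_group)
    ]
    group_of = {
        s: ("control" if s.startswith("ctrl") else "treated") for s in sample_ids
    }
    treated = np.array([group_of[s] == "treated" for s in sample_ids])

    scale = np.exp(rng.normal(0.0, config.sample_scale_sd, size=n_s))

    lo, hi = config.nb_mean_log_range
    sigma = _sigma_nat(config.nb_dispersion) / LN2  # in log2 units
    mag = config.de_log2fc_magnitude
    k = config.n_planted_triplets

    # per-class base abundances and DE assignment (fixed draw order)
    base: dict[str, np.ndarray] = {}
    de_features: dict[str, list[tuple[str, int]]] = {}
    de_sign: dict[str, np.ndarray] = {}
    for cls, n_feat in (("circRNA", config.n_circ), ("miRNA", config.n_mirna), ("mRNA", config.n_mrna)):
        shift = config.mirna_mean_log_shift if cls == "miRNA" else 0.0
        base[cls] = rng.uniform(lo + shift, hi + shift, size=n_feat)
        n_de = config.n_de_per_class.get(cls, 0)
        idx = rng.choice(n_feat, size=n_de, replace=False)
        signs = np.zeros(n_feat, dtype=int)
        # first k DE slots host the planted triplet members, alternating the
        # (circ UP, miR DOWN, mRNA UP) pattern with its mirror image
        for t in range(min(k, n_de)):
            pattern = 1 if t % 2 == 0 else -1
            s = pattern if cls != "miRNA" else -pattern
            signs[idx[t]] = s
        rest = idx[min(k, n_de):]
        signs[rest] = rng.choice([-1, 1], size=rest.size)
        de_sign[cls] = signs
        de_features[cls] = [(names[cls][i], int(signs[i])) for i in idx]
        # sponge-competent players are abundant: lift triplet members into the
        # top half of the abundance range
        if k > 0:
            base[cls][idx[:k]] = rng.uniform((lo + hi) / 2 + shift, hi + shift, size=min(k, n_de))

    triplets = [
        (de_features["circRNA"][t][0], de_features["miRNA"][t][0], de_features["mRNA"][t][0])
        for t in range(k)
    ]

    # shared latent factors: one per triplet per sample (log2 units, sd sigma)
    w = rng.normal(0.0, sigma, size=(k, n_s)) if k > 0 else np.zeros((0, n_s))
    c = config.coupling_strength
    resid = float(np.sqrt(max(0.0, 1.0 - c * c)))

    member_row = {
        cls: {de_features[cls][t][0]: t for t in range(k)} for cls in names
    }

    matrices: dict[str, CountMatrix] = {}
    for cls, n_feat in (("circRNA", config.n_circ), ("miRNA", config.n_mirna), ("mRNA", config.n_mrna)):
        log2mu = (base[cls][:, None] * np.log2(10.0)) + np.zeros((n_feat, n_s))
        signs = de_sign[cls]
        log2mu += np.where(treated[None, :], signs[:, None] * mag, 0.0)
        eps = rng.normal(0.0, sigma, size=(n_feat, n_s))
        noise = eps.copy()
        index_of = {fid: i for i, fid in enumerate(names[cls])}
        for fid, t in member_row[cls].items():
            i = index_of[fid]
            direction = -1.0 if cls == "miRNA" else 1.0
            noise[i] = direction * c * w[t] + resid * eps[i]
        # mean-one mixing in natural log space
        lam = np.exp2(log2mu + noise) * np.exp(-0.5 * (sigma * LN2) ** 2)
        lam = lam * scale[None, :]
        counts = rng.poisson(lam)
        matrices[cls] = CountMatrix(
            feature_ids=list(names[cls]),
            rna_class=cls,
            sample_ids=list(sample_ids),
            group_of=dict(group_of),
            counts=counts,
        )

    truth = PlantedTruth(de_features=de_features, triplets=triplets)
    return matrices["circRNA"], matrices["miRNA"], matrices["mRNA"], truth


# ---------------------------------------------------------------------------
# sequences

_SITE_SPAN = 14  # revcomp of miRNA positions 2-14, then the A opposite position 1


def simulate_sequences(
    config: SimulationConfig, truth: PlantedTruth
) -> dict[str, dict[str, str]]:
    """Random sequences with binding sites embedded for every planted pair.

    Each miRNA is a random 22-mer; each circRNA/mRNA gets a random sequence
    of ``utr_len``. For every planted (miRNA, target) pair the site embedded
    is the reverse complement of miRNA positions 2–14 followed by an adenine
    opposite position 1 — i.e. an 8mer seed site (recorded in
    ``truth.site_positions`` at the 8mer's offset) extended by 3'-supplementary
    pairing so that both the seed and the alignment detector fire. Besides
    each triplet's own miRNA, ``n_support_mirnas`` additional DE miRNAs gain
    sites in both the circRNA and the mRNA, emulating ceRNA pairs that share
    several response elements.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 2])
    names = feature_names(config)
    alphabet = np.array(list("ACGT"))

    def draw(n: int) -> str:
        return "".join(alphabet[rng.integers(0, 4, size=n)])

    mirna_seqs = {mid: draw(22) for mid in names["miRNA"]}
    target_seqs = {
        **{cid: draw(config.utr_len) for cid in names["circRNA"]},
        **{gid: draw(config.utr_len) for gid in names["mRNA"]},
    }

    # decide which (miRNA, target) pairs get planted sites
    planted_pairs: dict[str, list[str]] = {}  # target -> [mirna ids]
    de_mirs = truth.de_ids("miRNA")
    for circ, mir, mrna in truth.triplets:
        support_pool = [m for m in de_mirs if m != mir]
        n_sup = min(config.n_support_mirnas, len(support_pool))
        support = list(rng.choice(support_pool, size=n_sup, replace=False)) if n_sup else []
        for target in (circ, mrna):
            planted_pairs.setdefault(target, [])
            for m in [mir, *support]:
                if m not in planted_pairs[target]:
                    planted_pairs[target].append(m)

    truth.site_positions = []
    for target, mirs in planted_pairs.items():
        if config.utr_len < _SITE_SPAN * len(mirs):
            raise ConfigurationError(
                "utr_len too short to host all planted sites for one target"
            )
        seq = list(target_seqs[target])
        slot = config.utr_len // len(mirs)
        for j, mid in enumerate(mirs):
            mseq = mirna_seqs[mid]
            site = _revcomp(mseq[1:14]) + "A"
            start = j * slot + int(rng.integers(0, slot - len(site) + 1))
            seq[start : start + len(site)] = list(site)
            # the 8mer (revcomp of positions 2-8 plus the A) is the final 8 nt
            truth.site_positions.append((mid, target, start + len(site) - 8))
        target_seqs[target] = "".join(seq)

    return {
        "miRNA": mirna_seqs,
        "circRNA": {cid: target_seqs[cid] for cid in names["circRNA"]},
        "mRNA": {gid: target_seqs[gid] for gid in names["mRNA"]},
    }


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(config: SimulationConfig, truth: PlantedTruth) -> GeneSetCollection:
    """Background terms drawn uniformly over mRNAs plus direction-coherent
    planted terms that preferentially sample DE mRNAs (so m/n ≫ M/N)."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 3])
    mrna_ids = feature_names(config)["mRNA"]
    de = truth.de_features.get("mRNA", [])
    up = [fid for fid, s in de if s > 0]
    down = [fid for fid, s in de if s < 0]

    sets: list[tuple[str, str, list[str]]] = []
    planted_ids: list[str] = []
    for j in range(config.n_planted_terms):
        pool = up if (j % 2 == 0 and up) or not down else down
        n_core = min(12, len(pool))
        core = list(rng.choice(pool, size=n_core, replace=False)) if n_core else []
        n_pad = 4
        pad = list(rng.choice(mrna_ids, size=n_pad, replace=False))
        members = list(dict.fromkeys(core + pad))
        term = f"PLANTED_{j:02d}"
        direction = "up" if pool is up else "down"
        sets.append((term, f"planted {direction}-regulated module {j}", members))
        planted_ids.append(term)
    for j in range(config.n_background_terms):
        size = int(rng.integers(10, 41))
        members = list(rng.choice(mrna_ids, size=size, replace=False))
        sets.append((f"BG_{j:03d}", f"background term {j}", members))

    truth.enriched_terms = planted_ids
    return GeneSetCollection(sets=sets, universe=list(mrna_ids))
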