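"""Synthetic federated image datasets and synthetic ECG recordings.

Every downstream stage of the pipeline — domain discovery, multi-domain
classification, graph fine-tuning — is exercised on data from this
module, where the ground truth (domain membership, class rule, R-peak
locations) is known by construction.

The image federation emulates intra-client heterogeneity: each client
holds a mixture of K latent *domains*. A domain is a fixed geometric
template (a Walsh-type stripe pattern), and a sample is its template
plus i.i.d. Gaussian pixel noise. Class labels come from the mean
intensity of a small reserved patch; with ``conflicting_labels`` the
patch rule is inverted on alternating domains, so no single global
classifier that is linear in the pixels can fit all domains of a client
— exactly the pathology that per-domain heads resolve.

The ECG generator produces a quasi-periodic Gaussian-bump beat train
(P/QRS/T) at a configurable sampling rate with per-sample condition
tags, emulating the structure of chest-worn wearable recordings (one
subject per client, 700 Hz, baseline-vs-stress tags) without claiming
physiological realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SyntheticConfig",
    "ClientDataset",
    "FederatedDataset",
    "SyntheticECGRecord",
    "PatchClassRule",
    "make_domain_templates",
    "generate_client",
    "generate_federation",
    "generate_synthetic_ecg",
    "dominant_mixtures",
    "nearest_template_domains",
]


# ----------------------------------------------------------------- data types

@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic federation.

    domain_mixture is an (n_clients, n_domains_true) row-stochastic
    matrix; None means every client mixes domains uniformly.
    """

    n_clients: int = 4
    n_domains_true: int = 3
    samples_per_client: int = 150
    image_size: int = 16
    n_classes: int = 2
    domain_mixture: np.ndarray | None = None
    template_contrast: float = 1.0
    noise_sd: float = 0.05
    conflicting_labels: bool = False
    seed: int = 42

    def __post_init__(self):
        if self.n_domains_true < 2:
            raise ValueError("n_domains_true must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.domain_mixture is not None:
            m = np.asarray(self.domain_mixture, dtype=np.float64)
            if m.shape != (self.n_clients, self.n_domains_true):
                raise ValueError("domain_mixture must be (n_clients, n_domains_true)")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("domain_mixture rows must sum to 1")
            self.domain_mixture = m


@dataclass
class ClientDataset:
    """One client's local data: grayscale images in [0,1] plus labels."""

    images: np.ndarray                      # (n, H, W)
    class_labels: np.ndarray                # (n,) ints
    client_id: str
    true_domains: np.ndarray | None = None  # (n,) ints in {1..K_true}

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.class_labels = np.asarray(self.class_labels, dtype=np.intp)
        if self.images.ndim != 3:
            raise ValueError("images must be (n, H, W)")
        if len(self.images) != len(self.class_labels):
            raise ValueError("images and labels length mismatch")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("non-finite image values")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("image values must lie in [0,1]")
        if self.true_domains is not None:
            self.true_domains = np.asarray(self.true_domains, dtype=np.intp)
            if len(self.true_domains) != len(self.images):
                raise ValueError("true_domains length mismatch")

    def __len__(self):
        return len(self.images)


@dataclass
class FederatedDataset:
    clients: list[ClientDataset]
    n_domains_true: int | None = None
    label_rules: dict | None = None   # domain -> rule description (emitted by generator)

    def __post_init__(self):
        ids = [c.client_id for c in self.clients]
        if len(set(ids)) != len(ids):
            raise ValueError("client_ids must be unique")

    def __len__(self):
        return len(self.clients)

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"client_ids": [c.client_id for c in self.clients],
                    "n_domains_true": self.n_domains_true,
                    "label_rules": self.label_rules}
        for c in self.clients:
            payload = {"images": c.images, "class_labels": c.class_labels}
            if c.true_domains is not None:
                payload["true_domains"] = c.true_domains
            np.savez_compressed(directory / f"client_{c.client_id}.npz", **payload)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "FederatedDataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        clients = []
        for cid in manifest["client_ids"]:
            with np.load(directory / f"client_{cid}.npz") as npz:
                clients.append(ClientDataset(
                    images=npz["images"], class_labels=npz["class_labels"],
                    true_domains=npz["true_domains"] if "true_domains" in npz else None,
                    client_id=cid))
        return cls(clients, manifest.get("n_domains_true"), manifest.get("label_rules"))

    def export_png(self, directory):
        """Optional PNG dump of every image (runtime artifact, inspection only)."""
        from PIL import Image
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in self.clients:
            for i, img in enumerate(c.images):
                arr = np.clip(img * 255, 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(
                    directory / f"{c.client_id}_{i:05d}.png")


@dataclass
class SyntheticECGRecord:
    signal: np.ndarray
    fs: float
    true_peak_indices: np.ndarray
    condition_labels: np.ndarray   # per-sample string tags
    domain_regimes: np.ndarray     # per-sample regime ids

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.true_peak_indices = np.asarray(self.true_peak_indices, dtype=np.intp)
        if len(self.true_peak_indices) and (
                np.any(np.diff(self.true_peak_indices) <= 0)
                or self.true_peak_indices[0] < 0
                or self.true_peak_indices[-1] >= len(self.signal)):
            raise ValueError("true_peak_indices must be strictly increasing, in bounds")

    def save(self, csv_path):
        """Two-column CSV (time, amplitude) + JSON sidecar (fs, labels, peaks)."""
        csv_path = Path(csv_path)
        t = np.arange(len(self.signal)) / self.fs
        np.savetxt(csv_path, np.column_stack([t, self.signal]),
                   delimiter=",", header="time,amplitude", comments="")
        segments = _run_length(self.condition_labels, self.domain_regimes)
        sidecar = {"fs": self.fs,
                   "true_peak_indices": self.true_peak_indices.tolist(),
                   "segments": segments}
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, csv_path) -> "SyntheticECGRecord":
        csv_path = Path(csv_path)
        data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
        sidecar = json.loads(csv_path.with_suffix(".json").read_text())
        n = len(data)
        labels = np.empty(n, dtype=object)
        regimes = np.zeros(n, dtype=np.intp)
        for start, stop, lab, reg in sidecar["segments"]:
            labels[start:stop] = lab
            regimes[start:stop] = reg
        return cls(signal=data[:, 1], fs=sidecar["fs"],
                   true_peak_indices=np.asarray(sidecar["true_peak_indices"]),
                   condition_labels=labels, domain_regimes=regimes)


def _run_length(labels, regimes):
    segments = []
    n = len(labels)
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start] or regimes[i] != regimes[start]:
            segments.append([int(start), int(i), str(labels[start]), int(regimes[start])])
            start = i
    return segments


# ------------------------------------------------------------------ templates

def _walsh(size: int, k: int) -> np.ndarray:
    """Boolean stripe function: parity of the k-th dyadic band index."""
    idx = np.arange(size)
    return (idx * (2 ** k) // size) % 2 == 1


def _patch_slices(size: int) -> tuple[slice, slice]:
    """The reserved class patch: a central square of side size//4."""
    p = max(2, size // 4)
    lo = (size - p) // 2
    return slice(lo, lo + p), slice(lo, lo + p)


def make_domain_templates(n_domains: int, image_size: int, contrast: float,
                          seed: int = 0) -> list[np.ndarray]:
    """Distinct base images with guaranteed pairwise separation.

    Templates are Walsh-type stripe patterns (products of dyadic row and
    column parities) at intensity `contrast`; any two distinct patterns
    disagree on exactly half of the pixels (for power-of-two sizes), so
    the pairwise mean absolute difference is at least contrast/2. The
    candidate list is filtered greedily against that bound, which makes
    the guarantee exact rather than probabilistic; the seed is accepted
    for interface uniformity but the construction is deterministic. The
    central class patch is not carved out here — the label rule
    overwrites it at sample time.
    """
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    if not (0 < contrast <= 1):
        raise ValueError("contrast must lie in (0, 1]")
    max_k = int(np.log2(image_size))
    candidates = []
    for kr in range(max_k + 1):
        for kc in range(max_k + 1):
            if kr == 0 and kc == 0:
                continue
            candidates.append((kr + kc, kr, kc))
    candidates.sort()
    templates: list[np.ndarray] = []
    for _, kr, kc in candidates:
        row = _walsh(image_size, kr)[:, None]
        col = _walsh(image_size, kc)[None, :]
        pattern = np.logical_xor(row, col).astype(np.float64) * contrast
        ok = all(np.mean(np.abs(pattern - t)) >= contrast / 2 - 1e-12
                 for t in templates)
        if ok:
            templates.append(pattern)
        if len(templates) == n_domains:
            return templates
    raise ValueError(
        f"cannot construct {n_domains} templates with separation >= {contrast / 2} "
        f"at image_size {image_size}")


# ----------------------------------------------------------------- class rule

class PatchClassRule:
    """Class label from the reserved patch's mean intensity.

    The generator writes the patch at 0.5 +/- offset and the label is
    1 iff the patch is bright — inverted on odd domains when
    ``conflicting`` is set, so the label rule for domain d is the
    inversion of domain d+1's rule and one global linear head cannot fit
    both.
    """

    def __init__(self, image_size: int, conflicting: bool = False, offset: float = 0.25):
        self.slices = _patch_slices(image_size)
        self.conflicting = conflicting
        self.offset = offset

    def invert(self, domain: int) -> bool:
        """Whether the rule for this 1-based domain label is inverted."""
        return self.conflicting and (domain % 2 == 0)

    def apply(self, rng: np.random.Generator, image: np.ndarray, domain: int
              ) -> tuple[np.ndarray, int]:
        bright = bool(rng.integers(0, 2))
        rs, cs = self.slices
        image[rs, cs] = 0.5 + (self.offset if bright else -self.offset)
        label = int(bright) ^ int(self.invert(domain))
        return image, label

    def rule_table(self, n_domains: int) -> dict:
        return {str(d): {"bright_patch_means_class": 0 if self.invert(d) else 1}
                for d in range(1, n_domains + 1)}


# ----------------------------------------------------------------- generators

def generate_client(templates: Sequence[np.ndarray], mixture: Sequence[float],
                    n_samples: int, class_rule: PatchClassRule | None,
                    noise_sd: float, seed: int, client_id: str = "0") -> ClientDataset:
    """Sample one client: template mixture + Gaussian noise, clipped to [0,1]."""
    mixture = np.asarray(mixture, dtype=np.float64)
    if len(mixture) != len(templates):
        raise ValueError("mixture length must equal number of templates")
    if not np.isclose(mixture.sum(), 1.0, atol=1e-9):
        raise ValueError("mixture must sum to 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    domains = rng.choice(len(templates), size=n_samples, p=mixture) + 1  # 1-based
    images = np.empty((n_samples,) + templates[0].shape)
    labels = np.empty(n_samples, dtype=np.intp)
    for i, d in enumerate(domains):
        img = templates[d - 1].copy()
        if class_rule is not None:
            img, labels[i] = class_rule.apply(rng, img, int(d))
        else:
            labels[i] = 0
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        images[i] = np.clip(img, 0.0, 1.0)
    return ClientDataset(images=images, class_labels=labels,
                         true_domains=domains, client_id=client_id)


def dominant_mixtures(n_clients: int, n_domains: int, dominant: float = 0.85
                      ) -> np.ndarray:
    """Row-stochastic mixtures where client i leans on domain i mod K."""
    rest = (1.0 - dominant) / (n_domains - 1)
    m = np.full((n_clients, n_domains), rest)
    for i in range(n_clients):
        m[i, i % n_domains] = dominant
    return m


def generate_federation(config: SyntheticConfig) -> FederatedDataset:
    """Deterministic federation from a SyntheticConfig."""
    templates = make_domain_templates(config.n_domains_true, config.image_size,
                                      config.template_contrast, config.seed)
    rule = PatchClassRule(config.image_size, conflicting=config.conflicting_labels)
    if config.domain_mixture is None:
        mix = np.full((config.n_clients, config.n_domains_true),
                      1.0 / config.n_domains_true)
    else:
        mix = config.domain_mixture
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_clients)
    clients = [
        generate_client(templates, mix[i], config.samples_per_client, rule,
                        config.noise_sd, seed=int(seeds[i] % (2 ** 31)),
                        client_id=str(i))
        for i in range(config.n_clients)
    ]
    return FederatedDataset(clients, n_domains_true=config.n_domains_true,
                            label_rules=rule.rule_table(config.n_domains_true))


def nearest_template_domains(images: np.ndarray, templates: Sequence[np.ndarray]
                             ) -> np.ndarray:
    """Oracle domain classifier: nearest template in raw pixel space (1-based)."""
    flat = images.reshape(len(images), -1)
    t = np.stack([tmpl.ravel() for tmpl in templates])
    d2 = ((flat[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1


# ------------------------------------------------------------------------- ECG

# Per-beat Gaussian bumps (amplitude, center offset as fraction of RR,
# width in seconds). Regimes perturb the base morphology, giving each
# within-subject "regime" a distinct beat shape.
_BASE_BEAT = {"p": (0.15, -0.22, 0.022), "q": (-0.12, -0.028, 0.009),
              "r": (1.00, 0.0, 0.011), "s": (-0.22, 0.030, 0.010),
              "t": (0.32, 0.24, 0.045)}


def _regime_morphology(regime: int) -> dict:
    morph = {k: list(v) for k, v in _BASE_BEAT.items()}
    # deterministic per-regime deformation: T amplitude and R width shift
    morph["t"][0] *= 1.0 + 0.6 * (regime % 3 - 1)   # 0.4x .. 1.6x
    morph["r"][2] *= 1.0 + 0.25 * (regime % 2)
    morph["p"][0] *= 1.0 + 0.4 * ((regime // 2) % 2)
    return morph


def generate_synthetic_ecg(duration: float, fs: float, heart_rate: float,
                           regime_schedule: Sequence[tuple[float, int, str]] | None = None,
                           noise_sd: float = 0.0, seed: int = 0) -> SyntheticECGRecord:
    """Quasi-periodic Gaussian-bump beat train with known R-peak locations.

    regime_schedule is a list of (duration_s, regime_id, condition_tag)
    segments; each beat takes the morphology of the regime active at its
    R peak, and per-sample tags/regimes follow the schedule. Default: a
    single baseline regime for the whole record.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not (30 <= heart_rate <= 220):
        raise ValueError("heart_rate must lie in [30, 220] bpm")
    n = int(round(duration * fs))
    rr = 60.0 / heart_rate
    if duration < rr:
        raise ValueError("record shorter than one beat")
    if regime_schedule is None:
        regime_schedule = [(duration, 0, "baseline")]

    regimes = np.zeros(n, dtype=np.intp)
    labels = np.empty(n, dtype=object)
    labels[:] = regime_schedule[-1][2]
    start = 0.0
    for seg_dur, rid, tag in regime_schedule:
        lo, hi = int(round(start * fs)), min(int(round((start + seg_dur) * fs)), n)
        regimes[lo:hi] = rid
        labels[lo:hi] = tag
        start += seg_dur

    t = np.arange(n) / fs
    signal = np.zeros(n)
    peak_times = np.arange(rr / 2, duration - 1e-9, rr)
    peaks = np.round(peak_times * fs).astype(np.intp)
    peaks = peaks[peaks < n]
    for pk_t, pk_i in zip(peak_times, peaks):
        morph = _regime_morphology(int(regimes[pk_i]))
        window = np.abs(t - pk_t) < rr  # local support
        tw = t[window]
        for amp, off_frac, width in morph.values():
            center = pk_t + off_frac * rr
            signal[window] += amp * np.exp(-0.5 * ((tw - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return SyntheticECGRecord(signal=signal, fs=fs, true_peak_indices=peaks,
                              condition_labels=labels, domain_regimes=regimes)
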