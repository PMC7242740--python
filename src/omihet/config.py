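"""Pipeline configuration: a flat, diff-friendly key = value text format."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """All tunable knobs of the end-to-end pipeline, serializable round-trip."""

    seed: int = 0
    out_dir: str = "omihet_out"
    # simulation fixture
    n_patients: int = 2
    organoids_per_patient: int = 3
    image_size: int = 32
    cells_per_image: int = 3
    n_time_bins: int = 256
    bin_width_ns: float = 0.039
    irf_fwhm_ns: float = 0.25
    background_rate: float = 0.02
    photons_per_pixel: float = 5000.0
    treatment_name: str = "drugA"
    treatment_shift: float = -0.5  # per-endpoint, control-SD units
    # fitting
    bin_radius: int = 1
    min_photons: float = 500.0
    # segmentation
    smoothing_sigma: float = 2.0
    min_area: int = 20
    min_marker_distance: int = 5
    min_valid_pixels: int = 10
    # heterogeneity
    qe_bins: int = 20
    n_boot: int = 1000
    g_max: int = 3
    # response
    delta_threshold: float = 0.75

    def validate(self) -> None:
        if self.image_size < 16 or self.n_time_bins < 16:
            raise ValueError("image_size and n_time_bins must be >= 16")
        if self.bin_width_ns <= 0 or self.irf_fwhm_ns <= 0:
            raise ValueError("time calibration values must be positive")
        if not 1 <= self.g_max <= 3:
            raise ValueError("g_max must be 1..3")
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be positive")
        if self.min_photons < 0 or self.n_boot < 1:
            raise ValueError("min_photons >= 0 and n_boot >= 1 required")

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in types:
                raise ValueError(f"line {lineno}: unknown option {key!r}")
            kwargs[key] = casts[types[key]](value)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Short stable hash of the computational configuration.

        Stamped into every output header; excludes ``out_dir`` so the same
        analysis written to two locations carries the same fingerprint.
        """
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()[:12]
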