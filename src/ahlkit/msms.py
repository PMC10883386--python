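"""Precursor-ion-scan screening of MS/MS runs for acyl-homoserine lactones.

The screening chain mirrors the wet-lab analysis of unit-resolution
triple-quadrupole product-ion data:

1. read a run (mzML or MGF) of MS2 scans;
2. keep spectra containing the AHL-characteristic daughter ion m/z 102
   (the protonated homoserine-lactone ring);
3. confirm candidates by at least one further daughter at m/z 56, 74 or 84;
4. extract an EIC for each surviving precursor mass and detect peaks;
5. compare against a medium-control run and keep peaks that clearly exceed
   the control background;
6. annotate retained nominal masses against the theoretical library and
   cluster the final features in (m/z, retention time) space.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .masslib import Annotation, MassLibrary, annotate_mz

__all__ = [
    "FragmentPeak",
    "ProductSpectrum",
    "Run",
    "EIC",
    "ChromPeak",
    "CandidateFeature",
    "FeatureClustering",
    "ScreenParams",
    "read_run",
    "precursor_ion_screen",
    "confirm_daughters",
    "extract_eic",
    "detect_peaks",
    "control_compare",
    "screen_pipeline",
    "cluster_features",
    "features_to_frame",
]

#: Instrument acquisition mass range (amu) of the reference method.
INSTRUMENT_MASS_RANGE = (120.0, 450.0)


@dataclass(frozen=True)
class FragmentPeak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.intensity < 0:
            raise ValueError("fragment intensity must be non-negative")


@dataclass(frozen=True)
class ProductSpectrum:
    """One product-ion (MS2) scan: precursor, retention time, fragments."""

    precursor_mz: float
    retention_time: float  # minutes
    fragments: tuple[FragmentPeak, ...]
    scan_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "fragments",
            tuple(sorted(self.fragments, key=lambda p: p.mz)),
        )

    @property
    def in_mass_range(self) -> bool:
        lo, hi = INSTRUMENT_MASS_RANGE
        return lo <= self.precursor_mz <= hi

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.fragments), default=0.0)

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.fragments)


@dataclass(frozen=True)
class Run:
    """An ordered collection of product spectra from one extract."""

    spectra: tuple[ProductSpectrum, ...]
    label: Literal["sample", "control"]
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("sample", "control"):
            raise ValueError("run label must be 'sample' or 'control'")
        object.__setattr__(
            self,
            "spectra",
            tuple(sorted(self.spectra, key=lambda s: s.retention_time)),
        )

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def species(self) -> str:
        return self.metadata.get("species", self.label)

    @property
    def scan_times(self) -> np.ndarray:
        """Sorted unique scan times: the chromatographic time axis.

        Several product spectra (one per precursor) can share one scan
        time; chromatograms are defined on this deduplicated grid.
        """
        return np.unique([s.retention_time for s in self.spectra])


@dataclass(frozen=True)
class EIC:
    """Extracted ion chromatogram for one precursor mass."""

    target_mz: float
    tolerance: float
    retention_times: np.ndarray
    intensities: np.ndarray

    def __len__(self) -> int:
        return len(self.retention_times)


@dataclass(frozen=True)
class ChromPeak:
    apex_rt: float
    height: float
    area: float
    left_rt: float
    right_rt: float
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if not (self.left_rt < self.apex_rt <= self.right_rt):
            raise ValueError("peak bounds must satisfy left < apex <= right")
        if self.height <= 0:
            raise ValueError("peak height must be positive")


@dataclass(frozen=True)
class CandidateFeature:
    """A screened, confirmed, control-filtered (m/z, RT) feature."""

    mz: int
    retention_time: float
    sample: str
    daughters: frozenset[int]
    fold_change: float
    annotation: Annotation | None = None

    @property
    def annotation_name(self) -> str:
        if self.annotation is not None and self.annotation.best is not None:
            return self.annotation.best.name
        return ""

    @property
    def mass_error(self) -> float:
        if self.annotation is not None and self.annotation.matches:
            return self.annotation.matches[0][1]
        return float("nan")


@dataclass(frozen=True)
class FeatureClustering:
    features: tuple[CandidateFeature, ...]
    k: int
    labels: np.ndarray
    centers: np.ndarray  # standardized (m/z, RT) space
    inertia: float
    scale_mean: np.ndarray
    scale_std: np.ndarray


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of the screening chain (unit-resolution defaults)."""

    characteristic_mz: float = 102.0
    confirm_set: tuple[float, ...] = (56.0, 74.0, 84.0)
    fragment_tol: float = 0.5
    precursor_tol: float = 0.5
    min_rel_intensity: float = 0.01
    min_height: float = 1000.0
    min_snr: float = 3.0
    rt_window: float = 0.5
    fold_threshold: float = 3.0
    control_epsilon: float = 1.0
    annotation_tolerance: float = 0.5
    annotation_mode: Literal["nominal", "monoisotopic"] = "nominal"

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.precursor_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 <= self.min_rel_intensity < 1):
            raise ValueError("min_rel_intensity must lie in [0, 1)")
        if self.fold_threshold <= 0 or self.control_epsilon <= 0:
            raise ValueError("control thresholds must be positive")


# ---------------------------------------------------------------------------
# readers


def _rt_minutes(value, unit: str | None) -> float:
    if unit == "second":
        return float(value) / 60.0
    return float(value)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ElementTree.Element) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: (array kind, values)."""
    dtype = np.float64
    compressed = False
    kind: str | None = None
    payload = ""
    for child in bda.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectrum(elem: ElementTree.Element) -> ProductSpectrum | None:
    """Parse one mzML <spectrum> element; None for non-MS2 scans."""
    scan_id = elem.get("id", "")
    ms_level = None
    rt_value = None
    rt_unit = "minute"
    precursor = None
    arrays: dict[str, np.ndarray] = {}
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(child.get("value", "0"))
            elif acc == "MS:1000016":
                rt_value = child.get("value")
                rt_unit = child.get("unitName", "minute")
            elif acc == "MS:1000744":
                precursor = float(child.get("value", "nan"))
        elif name == "binaryDataArray":
            kind, values = _decode_binary_array(child)
            if kind is not None:
                arrays[kind] = values
    if ms_level != 2:
        return None
    if precursor is None or rt_value is None or "mz" not in arrays:
        raise ValueError(f"malformed mzML scan {scan_id!r}")
    intensities = arrays.get("intensity", np.zeros(len(arrays["mz"])))
    return ProductSpectrum(
        precursor_mz=precursor,
        retention_time=_rt_minutes(rt_value, rt_unit),
        fragments=tuple(
            FragmentPeak(float(m), float(v))
            for m, v in zip(arrays["mz"], intensities)
        ),
        scan_id=scan_id,
    )


def read_run(
    path: str | Path,
    fmt: Literal["mzML", "MGF", "auto"] = "auto",
    label: Literal["sample", "control"] = "sample",
    metadata: dict | None = None,
) -> Run:
    """Read an MS/MS run from mzML or MGF into a :class:`Run`.

    Retention times are normalized to minutes.  Files without MS2 scans
    produce an empty run with a warning; malformed files raise with the
    offending scan named where possible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = "mzML" if suffix == ".mzml" else "MGF" if suffix == ".mgf" else None
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path}")

    spectra: list[ProductSpectrum] = []
    if fmt == "mzML":
        try:
            for _event, elem in ElementTree.iterparse(str(path), events=("end",)):
                if _localname(elem.tag) != "spectrum":
                    continue
                s = _parse_mzml_spectrum(elem)
                if s is not None:
                    spectra.append(s)
                elem.clear()
        except ElementTree.ParseError as exc:
            raise ValueError(f"malformed mzML file {path}: {exc}") from exc
    else:  # MGF: every entry is an MS2 scan by construction
        with _mgf.read(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                title = str(params.get("title", f"index={i}"))
                try:
                    precursor = float(params["pepmass"][0])
                    rt = params.get("rtinseconds")
                    rt_min = float(rt) / 60.0 if rt is not None else 0.0
                except (KeyError, IndexError, TypeError, ValueError) as exc:
                    raise ValueError(f"malformed MGF scan {title!r} in {path}") from exc
                spectra.append(
                    ProductSpectrum(
                        precursor_mz=precursor,
                        retention_time=rt_min,
                        fragments=tuple(
                            FragmentPeak(float(m), float(v))
                            for m, v in zip(entry["m/z array"], entry["intensity array"])
                        ),
                        scan_id=title,
                    )
                )

    if not spectra:
        warnings.warn(f"no MS2 scans found in {path}", stacklevel=2)
    return Run(
        spectra=tuple(spectra),
        label=label,
        source=str(path),
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# screening stages


def _matching_fragment(
    spectrum: ProductSpectrum, target: float, tol: float, min_rel_intensity: float
) -> bool:
    gate = min_rel_intensity * spectrum.base_peak_intensity
    return any(
        abs(p.mz - target) <= tol and p.intensity >= gate for p in spectrum.fragments
    )


def precursor_ion_screen(
    run: Run,
    characteristic_mz: float = 102.0,
    tol: float = 0.5,
    min_rel_intensity: float = 0.01,
) -> list[ProductSpectrum]:
    """Keep spectra containing the characteristic daughter ion (m/z 102).

    A spectrum passes when it holds at least one fragment within ``tol`` of
    ``characteristic_mz`` whose intensity reaches ``min_rel_intensity`` of
    the spectrum's base peak.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not (0 <= min_rel_intensity < 1):
        raise ValueError("min_rel_intensity must lie in [0, 1)")
    return [
        s
        for s in run.spectra
        if _matching_fragment(s, characteristic_mz, tol, min_rel_intensity)
    ]


def confirm_daughters(
    spectrum: ProductSpectrum,
    confirm_set: Sequence[float] = (56.0, 74.0, 84.0),
    tol: float = 0.5,
    min_rel_intensity: float = 0.01,
) -> tuple[bool, frozenset[int]]:
    """Check for at least one confirmation daughter (m/z 56, 74 or 84).

    Returns the verdict together with the subset of confirmation masses
    observed, under the same tolerance/intensity rule as the 102 screen.
    """
    observed = frozenset(
        int(round(target))
        for target in confirm_set
        if _matching_fragment(spectrum, target, tol, min_rel_intensity)
    )
    return (len(observed) > 0, observed)


def extract_eic(run: Run, target_mz: float, tol: float = 0.5) -> EIC:
    """Extracted ion chromatogram for one precursor mass.

    In precursor-ion-scan data each product spectrum belongs to one
    precursor; the EIC point at a scan time is the summed fragment
    intensity of the spectra whose precursor lies within ``tol`` of
    ``target_mz`` at that time.  Zero points are kept so that the RT axis
    equals the run's (unique) scan times.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rts = run.scan_times
    index = {rt: i for i, rt in enumerate(rts)}
    ints = np.zeros(len(rts), dtype=float)
    for s in run.spectra:
        if abs(s.precursor_mz - target_mz) <= tol:
            ints[index[s.retention_time]] += s.total_intensity
    return EIC(target_mz=target_mz, tolerance=tol, retention_times=rts, intensities=ints)


def detect_peaks(
    eic: EIC, min_height: float = 1000.0, min_snr: float = 3.0
) -> list[ChromPeak]:
    """Find significant chromatographic peaks in an EIC.

    A peak is a local maximum above ``min_height`` and above ``min_snr``
    times a median-absolute-deviation noise floor; its bounds extend to the
    nearest valleys (or trace edges).
    """
    if len(eic) == 0:
        raise ValueError("empty EIC")
    y = eic.intensities
    rt = eic.retention_times
    if not np.any(y > 0):
        return []
    mad = float(np.median(np.abs(y - np.median(y))))
    floor = max(min_height, min_snr * 1.4826 * mad)
    idx, _ = find_peaks(y, height=floor)
    # a single-point trace or a plateau at the edge: fall back to argmax
    if len(idx) == 0 and float(np.max(y)) >= floor:
        idx = np.array([int(np.argmax(y))])

    peaks: list[ChromPeak] = []
    for i in idx:
        left = i
        while left > 0 and y[left - 1] < y[left] and y[left - 1] > 0:
            left -= 1
        right = i
        while right < len(y) - 1 and y[right + 1] < y[right] and y[right + 1] > 0:
            right += 1
        left = max(left - 1, 0)
        right = min(right + 1, len(y) - 1)
        if rt[left] >= rt[i]:
            left = max(i - 1, 0)
        area = float(np.trapezoid(y[left : right + 1], rt[left : right + 1]))
        peaks.append(
            ChromPeak(
                apex_rt=float(rt[i]),
                height=float(y[i]),
                area=area,
                left_rt=float(rt[left]) if rt[left] < rt[i] else float(rt[i]) - 1e-9,
                right_rt=float(rt[right]),
            )
        )
    return peaks


def control_compare(
    sample_peaks: Sequence[ChromPeak],
    control_run: Run,
    target_mz: float,
    tol: float = 0.5,
    rt_window: float = 0.5,
    fold_threshold: float = 3.0,
    epsilon: float = 1.0,
) -> list[ChromPeak]:
    """Retain sample peaks that exceed the medium-control background.

    A sample peak survives when its height is at least ``fold_threshold``
    times the maximum control EIC intensity at the same mass within
    ``rt_window`` minutes of the apex (floored at ``epsilon`` to avoid
    division by zero).  Retained peaks carry their fold-change.
    """
    if control_run.label != "control":
        raise ValueError("control_compare requires a run labeled 'control'")
    ctrl = extract_eic(control_run, target_mz, tol)
    retained: list[ChromPeak] = []
    for peak in sample_peaks:
        mask = np.abs(ctrl.retention_times - peak.apex_rt) <= rt_window
        ctrl_max = float(np.max(ctrl.intensities[mask])) if np.any(mask) else 0.0
        fold = peak.height / max(ctrl_max, epsilon)
        if fold >= fold_threshold:
            retained.append(replace(peak, fold_change=fold))
    return retained


@dataclass(frozen=True)
class StageCounts:
    """Per-stage bookkeeping of the screening chain."""

    scanned: int
    screened: int
    confirmed: int
    candidate_masses: int
    peaks: int
    retained: int
    features: int


def screen_pipeline(
    sample: Run,
    control: Run,
    library: MassLibrary,
    params: ScreenParams | None = None,
) -> tuple[list[CandidateFeature], StageCounts]:
    """Run screen -> confirm -> EIC/peaks -> control comparison -> annotate.

    Returns one :class:`CandidateFeature` per retained (nominal mass, apex)
    pair, deterministically ordered by (m/z, RT), plus per-stage counts.
    """
    p = params or ScreenParams()
    screened = precursor_ion_screen(
        sample, p.characteristic_mz, p.fragment_tol, p.min_rel_intensity
    )
    confirmed: list[tuple[ProductSpectrum, frozenset[int]]] = []
    for s in screened:
        ok, observed = confirm_daughters(
            s, p.confirm_set, p.fragment_tol, p.min_rel_intensity
        )
        if ok:
            confirmed.append((s, observed))

    masses = sorted({int(round(s.precursor_mz)) for s, _ in confirmed})
    features: list[CandidateFeature] = []
    n_peaks = 0
    n_retained = 0
    for mass in masses:
        eic = extract_eic(sample, float(mass), p.precursor_tol)
        peaks = detect_peaks(eic, p.min_height, p.min_snr)
        n_peaks += len(peaks)
        kept = control_compare(
            peaks,
            control,
            float(mass),
            tol=p.precursor_tol,
            rt_window=p.rt_window,
            fold_threshold=p.fold_threshold,
            epsilon=p.control_epsilon,
        )
        n_retained += len(kept)
        for peak in kept:
            daughters: set[int] = set()
            for s, observed in confirmed:
                if (
                    int(round(s.precursor_mz)) == mass
                    and peak.left_rt <= s.retention_time <= peak.right_rt
                ):
                    daughters |= observed
            if not daughters:
                continue  # peak without any confirmed scan inside its bounds
            annotation = annotate_mz(
                float(mass), library, p.annotation_tolerance, p.annotation_mode
            )
            features.append(
                CandidateFeature(
                    mz=mass,
                    retention_time=peak.apex_rt,
                    sample=sample.species,
                    daughters=frozenset(daughters),
                    fold_change=peak.fold_change or float("inf"),
                    annotation=annotation,
                )
            )
    features.sort(key=lambda f: (f.mz, f.retention_time))
    counts = StageCounts(
        scanned=len(sample),
        screened=len(screened),
        confirmed=len(confirmed),
        candidate_masses=len(masses),
        peaks=n_peaks,
        retained=n_retained,
        features=len(features),
    )
    return features, counts


def features_to_frame(features: Sequence[CandidateFeature]) -> pd.DataFrame:
    """Stable tabular form of a feature list (the features CSV layout)."""
    return pd.DataFrame(
        {
            "species": [f.sample for f in features],
            "mz": [f.mz for f in features],
            "rt": [round(f.retention_time, 4) for f in features],
            "daughters": [
                ";".join(str(d) for d in sorted(f.daughters)) for f in features
            ],
            "fold_change": [round(f.fold_change, 4) for f in features],
            "annotation": [f.annotation_name for f in features],
            "mass_error": [round(f.mass_error, 4) for f in features],
        }
    )


def cluster_features(
    features: Sequence[CandidateFeature],
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> FeatureClustering:
    """k-means clustering of features in z-standardized (m/z, RT) space.

    The default k of four reflects the grouping observed when compounds
    from several producer species are plotted by mass and retention time.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(features) < k:
        raise ValueError(f"need at least k={k} features, got {len(features)}")
    X = np.array([[f.mz, f.retention_time] for f in features], dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    return FeatureClustering(
        features=tuple(features),
        k=k,
        labels=labels,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        scale_mean=mean,
        scale_std=std,
    )
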