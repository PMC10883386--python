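"""Synthetic inputs with planted ground truth for both pipeline tracks.

Two generators:

* :func:`make_ms_run` emulates precursor-ion-scan acquisition on a
  unit-resolution triple quadrupole: planted AHLs elute as Gaussian
  profiles and yield product spectra containing the m/z 102 ring ion plus
  a non-empty subset of the confirmation daughters {56, 74, 84}; decoy
  spectra come in two kinds (no 102 at all; 102 without any confirmation
  daughter); medium-background ions appear in both the sample and the
  control run at matched intensity.  Runs are written as mzML and MGF.

* :func:`make_cohort` emulates a genome-mining campaign over many
  assemblies: per-assembly hmmsearch ``--tblout`` tables with planted
  significant hits, above-threshold decoy rows and multi-model collision
  rows, duplicate species across assemblies, manifests, and a BLAST
  tabular file — each with a truth table recording what was planted.

Both generators are pure functions of their spec (seed included): the same
spec yields byte-identical files.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from . import masslib
from .msms import FragmentPeak, ProductSpectrum, Run

__all__ = [
    "PlantedAHL",
    "BackgroundIon",
    "MsRunSpec",
    "MsRunResult",
    "make_ms_run",
    "CohortSpec",
    "CohortResult",
    "make_cohort",
    "write_mzml",
    "write_mgf",
]

RING_MZ = 102.055  # protonated homoserine-lactone ring, monoisotopic
CONFIRM_MZS = (56.05, 74.06, 84.04)


@dataclass(frozen=True)
class PlantedAHL:
    """One spiked compound: library name, elution apex and shape."""

    name: str  # canonical AHL name, e.g. "C8-HSL"
    rt: float  # apex retention time, minutes
    apex_intensity: float = 5e4
    width: float = 0.1  # Gaussian sigma, minutes


@dataclass(frozen=True)
class BackgroundIon:
    """A medium-background ion present in both sample and control."""

    mz: float
    rt: float
    apex_intensity: float = 3e4
    width: float = 0.15
    ahl_like: bool = True  # carries 102 + confirmation daughters


@dataclass(frozen=True)
class MsRunSpec:
    """Study conditions of one synthetic sample/control acquisition."""

    planted: tuple[PlantedAHL, ...] = ()
    background: tuple[BackgroundIon, ...] = ()
    n_decoys_no102: int = 10
    n_decoys_noconfirm: int = 5
    noise_fragments_lambda: float = 0.0  # Poisson count of chemical-noise fragments
    noise_rel_intensity: float = 0.02  # relative to the scan base peak
    intensity_jitter: float = 0.0  # lognormal sigma on fragment intensities
    rt_min: float = 0.0
    rt_max: float = 40.0  # gradient span of the reference method
    scan_interval: float = 0.05  # minutes
    species: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_min >= self.rt_max:
            raise ValueError("rt_min must be < rt_max")
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be positive")
        for p in self.planted:
            if not (self.rt_min <= p.rt <= self.rt_max):
                raise ValueError(
                    f"planted RT {p.rt} outside gradient span "
                    f"[{self.rt_min}, {self.rt_max}]"
                )
        for b in self.background:
            if not (self.rt_min <= b.rt <= self.rt_max):
                raise ValueError("background RT outside gradient span")


@dataclass(frozen=True)
class MsRunResult:
    sample: Run
    control: Run
    truth: pd.DataFrame
    files: dict[str, Path] = field(default_factory=dict)


def _lognormal(rng: np.random.Generator, base: float, sigma: float) -> float:
    if sigma <= 0:
        return base
    return float(base * rng.lognormal(0.0, sigma))


def _elution_spectra(
    mz: float,
    rt: float,
    apex: float,
    width: float,
    scan_times: np.ndarray,
    daughters: Sequence[float],
    rng: np.random.Generator,
    spec: MsRunSpec,
    tag: str,
) -> list[ProductSpectrum]:
    """Product spectra across a Gaussian elution profile at one precursor."""
    out: list[ProductSpectrum] = []
    profile = apex * np.exp(-0.5 * ((scan_times - rt) / width) ** 2)
    for t, inten in zip(scan_times, profile):
        if inten < max(1.0, 1e-4 * apex):
            continue
        frags = [FragmentPeak(RING_MZ, _lognormal(rng, inten, spec.intensity_jitter))]
        for i, dmz in enumerate(daughters):
            frac = 0.25 + 0.15 * i
            frags.append(
                FragmentPeak(dmz, _lognormal(rng, frac * inten, spec.intensity_jitter))
            )
        n_noise = int(rng.poisson(spec.noise_fragments_lambda))
        for _ in range(n_noise):
            nmz = float(rng.uniform(50.0, max(mz - 1.0, 51.0)))
            frags.append(
                FragmentPeak(
                    nmz,
                    _lognormal(rng, spec.noise_rel_intensity * inten, 0.5),
                )
            )
        out.append(
            ProductSpectrum(
                precursor_mz=mz,
                retention_time=float(t),
                fragments=tuple(frags),
                scan_id=f"{tag}_rt{t:.3f}",
            )
        )
    return out


def make_ms_run(spec: MsRunSpec, out_dir: str | Path | None = None) -> MsRunResult:
    """Generate a sample run, a matched medium-control run, and the truth.

    Decoy precursor masses are drawn away from every planted/background
    nominal mass (at least 2 m/z units) so that planted EICs stay clean.
    When ``out_dir`` is given, each run is written as both mzML and MGF
    along with a ``truth.csv``.
    """
    rng = np.random.default_rng(spec.seed)
    scan_times = np.round(
        np.arange(spec.rt_min, spec.rt_max, spec.scan_interval), 6
    )
    library = masslib.build_library()

    truth_rows: list[dict] = []
    sample_spectra: list[ProductSpectrum] = []
    control_spectra: list[ProductSpectrum] = []
    reserved: set[int] = set()

    for p in spec.planted:
        species = masslib.AHLSpecies.from_descriptor(masslib.parse_name(p.name))
        mz = species.monoisotopic_mh
        reserved.add(species.nominal_mh)
        # fixed non-empty confirmation subset per compound
        n_conf = int(rng.integers(1, len(CONFIRM_MZS) + 1))
        idx = sorted(rng.choice(len(CONFIRM_MZS), size=n_conf, replace=False))
        daughters = [CONFIRM_MZS[i] for i in idx]
        sample_spectra.extend(
            _elution_spectra(
                mz, p.rt, p.apex_intensity, p.width, scan_times, daughters,
                rng, spec, f"ahl_{p.name}",
            )
        )
        truth_rows.append(
            {
                "kind": "ahl",
                "name": p.name,
                "nominal_mz": species.nominal_mh,
                "rt": p.rt,
                "apex_intensity": p.apex_intensity,
                "daughters": ";".join(str(int(round(d))) for d in daughters),
            }
        )

    for b in spec.background:
        reserved.add(int(round(b.mz)))
        daughters = list(CONFIRM_MZS) if b.ahl_like else []
        for target, tag in ((sample_spectra, "bg_s"), (control_spectra, "bg_c")):
            target.extend(
                _elution_spectra(
                    b.mz, b.rt, b.apex_intensity, b.width, scan_times,
                    daughters, rng, spec, f"{tag}_{b.mz:.0f}",
                )
            )
        truth_rows.append(
            {
                "kind": "background",
                "name": f"bg_{b.mz:.0f}",
                "nominal_mz": int(round(b.mz)),
                "rt": b.rt,
                "apex_intensity": b.apex_intensity,
                "daughters": "",
            }
        )

    def _decoy_mz() -> float:
        while True:
            cand = float(rng.uniform(150.0, 430.0))
            if all(abs(cand - r) >= 2.0 for r in reserved):
                return cand

    for kind, count in (
        ("decoy_no102", spec.n_decoys_no102),
        ("decoy_noconfirm", spec.n_decoys_noconfirm),
    ):
        for i in range(count):
            mz = _decoy_mz()
            rt = float(rng.uniform(spec.rt_min, spec.rt_max))
            rt = float(scan_times[np.argmin(np.abs(scan_times - rt))])
            inten = float(rng.uniform(2e3, 2e4))
            frags = []
            if kind == "decoy_noconfirm":
                frags.append(FragmentPeak(RING_MZ, inten))
            # filler fragments clear of 102 and the confirmation windows
            for _ in range(3):
                while True:
                    fmz = float(rng.uniform(110.0, max(mz - 1.0, 111.0)))
                    if abs(fmz - 102.0) > 1.0:
                        break
                frags.append(FragmentPeak(fmz, float(rng.uniform(0.2, 1.0)) * inten))
            sample_spectra.append(
                ProductSpectrum(
                    precursor_mz=mz,
                    retention_time=rt,
                    fragments=tuple(frags),
                    scan_id=f"{kind}_{i}",
                )
            )
            truth_rows.append(
                {
                    "kind": kind,
                    "name": f"{kind}_{i}",
                    "nominal_mz": int(round(mz)),
                    "rt": rt,
                    "apex_intensity": inten,
                    "daughters": "",
                }
            )

    sample = Run(
        spectra=tuple(sample_spectra),
        label="sample",
        metadata={"species": spec.species, "seed": spec.seed},
    )
    control = Run(
        spectra=tuple(control_spectra),
        label="control",
        metadata={"species": "medium control", "seed": spec.seed},
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "name", "nominal_mz", "rt", "apex_intensity", "daughters"],
    )

    files: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for run, stem in ((sample, "sample"), (control, "control")):
            files[f"{stem}_mzml"] = out_dir / f"{stem}.mzML"
            write_mzml(run, files[f"{stem}_mzml"])
            files[f"{stem}_mgf"] = out_dir / f"{stem}.mgf"
            write_mgf(run, files[f"{stem}_mgf"])
        files["truth"] = out_dir / "truth.csv"
        truth.to_csv(files["truth"], index=False)
    return MsRunResult(sample=sample, control=control, truth=truth, files=files)


# ---------------------------------------------------------------------------
# writers


def _b64_doubles(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a run as minimal mzML 1.1.0 (MS2 scans, 64-bit, uncompressed).

    The output is deliberately small but standard enough for any compliant
    reader; :func:`ahlkit.msms.read_run` round-trips it exactly.
    """
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <cvList count="1">',
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "  </cvList>",
        f'  <run id="{run.species}" defaultInstrumentConfigurationRef="IC1">',
        f'    <spectrumList count="{len(run.spectra)}">',
    ]
    for i, s in enumerate(run.spectra):
        mzs = [p.mz for p in s.fragments]
        ints = [p.intensity for p in s.fragments]
        mz_b64 = _b64_doubles(mzs)
        int_b64 = _b64_doubles(ints)
        lines += [
            f'      <spectrum index="{i}" id="scan={i}" defaultArrayLength="{len(mzs)}">',
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>',
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
            '        <scanList count="1">',
            "          <scan>",
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.retention_time:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>',
            "          </scan>",
            "        </scanList>",
            '        <precursorList count="1">',
            "          <precursor>",
            '            <selectedIonList count="1">',
            "              <selectedIon>",
            f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
            "              </selectedIon>",
            "            </selectedIonList>",
            "          </precursor>",
            "        </precursorList>",
            '        <binaryDataArrayList count="2">',
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
            f"            <binary>{mz_b64}</binary>",
            "          </binaryDataArray>",
            f'          <binaryDataArray encodedLength="{len(int_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>',
            f"            <binary>{int_b64}</binary>",
            "          </binaryDataArray>",
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))


def write_mgf(run: Run, path: str | Path) -> None:
    """Write a run as MGF (PEPMASS / RTINSECONDS headers)."""
    entries = [
        {
            "m/z array": np.array([p.mz for p in s.fragments]),
            "intensity array": np.array([p.intensity for p in s.fragments]),
            "params": {
                "title": s.scan_id or f"scan={i}",
                "pepmass": round(s.precursor_mz, 6),
                "rtinseconds": round(s.retention_time * 60.0, 4),
            },
        }
        for i, s in enumerate(run.spectra)
    ]
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# genome-mining cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic genome-mining cohort.

    Copy-number distributions are loosely shaped to the observed genus-wide
    statistics (synthase median ~5, receptor median ~123): synthase counts
    are 1 + Poisson(4.3) and receptor counts are a rounded Normal(123, 25)
    floored at 5.  These are fixture choices, not biological claims.
    """

    n_species: int = 200
    duplicate_fraction: float = 0.1
    synthase_lambda: float = 4.3
    receptor_mu: float = 123.0
    receptor_sigma: float = 25.0
    receptor_min: int = 5
    sig_evalue_range: tuple[float, float] = (1e-30, 1e-6)
    decoy_evalue_range: tuple[float, float] = (1e-4, 1.0)
    decoys_per_assembly: float = 5.0  # Poisson mean
    collision_rate: float = 0.1  # fraction of targets hit by a second model
    n_synthase_models: int = 3
    n_receptor_models: int = 5
    decoy_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not (0 <= self.duplicate_fraction <= 1):
            raise ValueError("duplicate_fraction must lie in [0, 1]")
        if not (0 <= self.collision_rate <= 1):
            raise ValueError("collision_rate must lie in [0, 1]")
        lo, hi = self.sig_evalue_range
        if not (0 < lo < hi <= 1e-5):
            raise ValueError("sig_evalue_range must lie strictly below 1e-5")
        dlo, dhi = self.decoy_evalue_range
        if not (1e-5 <= dlo < dhi):
            raise ValueError("decoy_evalue_range must lie at or above 1e-5")


@dataclass(frozen=True)
class CohortResult:
    tblout_dir: Path | None
    model_manifest: dict[str, str]
    assembly_universe: dict[str, str]
    tblout_texts: dict[str, str]  # assembly_id -> file content
    blast_text: str
    blast_species: dict[str, str]
    truth: pd.DataFrame  # per-assembly planted counts (+ dedup winner flag)
    blast_truth: dict
    files: dict[str, Path] = field(default_factory=dict)


_TBLOUT_HEADER = (
    "#                                                               "
    "--- full sequence ---- --- best 1 domain ---- --- domain number estimation ----\n"
    "# target name        accession  query name           accession  "
    "  E-value  score  bias     E-value  score  bias   exp reg clu  ov env dom rep inc "
    "description of target\n"
    "#------------------- ---------- -------------------- ---------- "
    "--------- ------ ----- --------- ------ ----- --- --- --- --- --- --- --- --- "
    "---------------------\n"
)


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def make_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> CohortResult:
    """Generate tblout tables, manifests, a BLAST table, and the truth.

    Every planted copy appears as one significant tblout row; a configured
    fraction of targets additionally gets a collision row from a second
    model at a worse E-value; decoy rows sit above the significance
    threshold.  Duplicate species share a species name across assemblies
    with independently drawn copy numbers; the truth table flags the
    assembly the dedup-by-product rule should keep.
    """
    rng = np.random.default_rng(spec.seed)

    syn_models = [f"SYNTHASE_HMM_{i:02d}" for i in range(spec.n_synthase_models)]
    rec_models = [f"RECEPTOR_HMM_{i:02d}" for i in range(spec.n_receptor_models)]
    manifest = {m: "synthase" for m in syn_models}
    manifest.update({m: "receptor" for m in rec_models})

    assemblies: list[tuple[str, str]] = []  # (assembly_id, species_name)
    asm_counter = 0
    for i in range(spec.n_species):
        species = f"Streptomyces syntheticus-{i:04d}"
        n_asm = 2 if rng.random() < spec.duplicate_fraction else 1
        for _ in range(n_asm):
            assemblies.append((f"GCF_SYN{asm_counter:06d}.1", species))
            asm_counter += 1

    truth_rows = []
    tblout_texts: dict[str, str] = {}
    for assembly_id, species in assemblies:
        if spec.decoy_only:
            n_syn, n_rec = 0, 0
        else:
            n_syn = 1 + int(rng.poisson(spec.synthase_lambda))
            n_rec = max(
                spec.receptor_min,
                int(round(rng.normal(spec.receptor_mu, spec.receptor_sigma))),
            )
        rows = []
        prot = 0
        for family_models, count in ((syn_models, n_syn), (rec_models, n_rec)):
            for _ in range(count):
                target = f"{assembly_id}_prot{prot:05d}"
                prot += 1
                model = family_models[int(rng.integers(len(family_models)))]
                ev = float(_loguniform(rng, *spec.sig_evalue_range))
                score = -10.0 * np.log10(ev) + float(rng.normal(0, 2))
                rows.append((target, model, ev, score))
                if len(family_models) > 1 and rng.random() < spec.collision_rate:
                    other = family_models[int(rng.integers(len(family_models)))]
                    if other == model:
                        other = family_models[
                            (family_models.index(model) + 1) % len(family_models)
                        ]
                    ev2 = float(ev * 10 ** rng.uniform(1.0, 6.0))
                    rows.append((target, other, ev2, score - 10.0))
        n_decoys = int(rng.poisson(spec.decoys_per_assembly))
        all_models = syn_models + rec_models
        for d in range(n_decoys):
            target = f"{assembly_id}_decoy{d:04d}"
            model = all_models[int(rng.integers(len(all_models)))]
            ev = float(_loguniform(rng, *spec.decoy_evalue_range))
            rows.append((target, model, ev, max(5.0, -10.0 * np.log10(max(ev, 1e-12)))))

        body = "".join(
            f"{t:<20s} -          {m:<20s} -          "
            f"{e:9.2g} {s:6.1f}   0.0 {e:9.2g} {s:6.1f}   0.0 "
            f"1.0 1 0 0 1 1 1 1 -\n"
            for t, m, e, s in rows
        )
        tblout_texts[assembly_id] = _TBLOUT_HEADER + body
        truth_rows.append(
            {
                "assembly_id": assembly_id,
                "species_name": species,
                "luxI_count": n_syn,
                "luxR_count": n_rec,
                "product": n_syn * n_rec,
            }
        )

    truth = pd.DataFrame(truth_rows)
    # flag the assembly the dedup rule keeps: max product, then max luxR,
    # then smallest assembly_id (computed directly from the planted counts)
    winners = set()
    for _, grp in truth.groupby("species_name"):
        ordered = grp.sort_values(
            by=["product", "luxR_count", "assembly_id"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        winners.add(ordered.iloc[0]["assembly_id"])
    truth["dedup_winner"] = truth["assembly_id"].isin(winners)

    # BLAST table: mixed significant / non-significant hits over a species subset
    n_blast = 40
    blast_lines = []
    blast_species: dict[str, str] = {}
    n_sig = 0
    sig_species: set[str] = set()
    for j in range(n_blast):
        subject = f"WP_SYN{j:06d}.1"
        sp_idx = int(rng.integers(spec.n_species))
        species = f"Streptomyces syntheticus-{sp_idx:04d}"
        blast_species[subject] = species
        significant = rng.random() < 0.7
        ev = float(
            _loguniform(rng, 1e-40, 9e-3) if significant else _loguniform(rng, 0.011, 10.0)
        )
        if significant:
            n_sig += 1
            sig_species.add(species)
        pident = float(rng.uniform(20.0, 60.0))
        length = int(rng.integers(60, 250))
        qstart = int(rng.integers(1, 30))
        qend = qstart + length - 1
        blast_lines.append(
            f"LuxR_query\t{subject}\t{pident:.2f}\t{length}\t"
            f"{int(length * (1 - pident / 100))}\t0\t{qstart}\t{qend}\t1\t{length}\t"
            f"{ev:.3g}\t{float(50 + rng.uniform(0, 100)):.1f}"
        )
    blast_text = "\n".join(blast_lines) + "\n"
    blast_truth = {"n_hits": n_blast, "n_significant": n_sig,
                   "n_unique_species": len(sig_species)}

    files: dict[str, Path] = {}
    tblout_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        tblout_dir = out_dir / "tblout"
        tblout_dir.mkdir(parents=True, exist_ok=True)
        for assembly_id, text in tblout_texts.items():
            (tblout_dir / f"{assembly_id}.tblout").write_text(text)
        files["models"] = out_dir / "models.tsv"
        files["models"].write_text(
            "".join(f"{m}\t{f}\n" for m, f in sorted(manifest.items()))
        )
        files["assemblies"] = out_dir / "assemblies.tsv"
        files["assemblies"].write_text(
            "".join(f"{a}\t{s}\n" for a, s in assemblies)
        )
        files["blast"] = out_dir / "blast.tsv"
        files["blast"].write_text(blast_text)
        files["blast_species"] = out_dir / "blast_species.tsv"
        files["blast_species"].write_text(
            "".join(f"{k}\t{v}\n" for k, v in sorted(blast_species.items()))
        )
        files["truth"] = out_dir / "truth.csv"
        truth.to_csv(files["truth"], index=False)

    return CohortResult(
        tblout_dir=tblout_dir,
        model_manifest=manifest,
        assembly_universe=dict(assemblies),
        tblout_texts=tblout_texts,
        blast_text=blast_text,
        blast_species=blast_species,
        truth=truth,
        blast_truth=blast_truth,
        files=files,
    )
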