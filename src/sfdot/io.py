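"""Dataset interchange and the end-to-end pipeline driver.

Datasets travel as one multi-page 16-bit grayscale TIFF stack plus a JSON
metadata sidecar ("sfdot-dataset v1").  Page order is frozen: for each
spatial frequency (ascending) the three phase frames in configured order,
followed by one bright-field page per frequency.  Lengths are mm, spatial
frequencies f are mm^-1, angles radians, everywhere.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from .demodulate import three_phase_demodulate
from .diffusion import MediumPair, OpticalProperties
from .margins import projection_width
from .phantom import AcquisitionDataset
from .targets import analyze_targets

__all__ = ["save_dataset", "load_dataset", "run_reconstruct", "DatasetFormatError"]

log = logging.getLogger(__name__)

SCHEMA = "sfdot-dataset v1"


class DatasetFormatError(ValueError):
    """Raised when a stack and its metadata disagree or fields are missing."""


def _medium_to_dict(medium: MediumPair) -> dict:
    def props(p: OpticalProperties) -> dict:
        return {"mu_a": p.mu_a, "mu_s_prime": p.mu_s_prime, "n_rel": p.n_rel}

    return {"ex": props(medium.ex), "em": props(medium.em)}


def _medium_from_dict(d: dict) -> MediumPair:
    return MediumPair(
        ex=OpticalProperties(**d["ex"]),
        em=OpticalProperties(**d["em"]),
    )


def save_dataset(dataset: AcquisitionDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tif`` (uint16 stack) and ``<prefix>.json`` (metadata).

    Frames are rounded/clipped to 16-bit counts; the roundtrip is bit-exact
    for camera-quantized datasets.
    """
    prefix = Path(prefix)
    stack_path = prefix.with_suffix(".tif")
    meta_path = prefix.with_suffix(".json")
    nf, nph = dataset.n_frequencies, len(dataset.phases)
    ny, nx = dataset.frames.shape[2:]
    pages = np.empty((nf * nph + nf, ny, nx), dtype=np.uint16)
    for i in range(nf):
        for j in range(nph):
            pages[i * nph + j] = np.clip(np.rint(dataset.frames[i, j].astype(float)), 0, 65535)
    for i in range(nf):
        pages[nf * nph + i] = np.clip(np.rint(dataset.brightfield[i].astype(float)), 0, 65535)
    tifffile.imwrite(stack_path, pages, photometric="minisblack")
    meta = {
        "schema": SCHEMA,
        "frequencies_mm^-1": list(map(float, dataset.frequencies)),
        "phases_rad": list(map(float, dataset.phases)),
        "pixel_pitch_mm": dataset.pixel_pitch,
        "exposure": dataset.exposure,
        "medium": _medium_to_dict(dataset.medium),
        "provenance": dataset.provenance,
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return stack_path, meta_path


def load_dataset(stack_path: str | Path, meta_path: str | Path | None = None) -> AcquisitionDataset:
    """Read a stack + sidecar back into an :class:`AcquisitionDataset`.

    Counts are converted to float; frequencies are reported ascending (frames
    are reordered if the metadata lists them unsorted).  Page-count or schema
    mismatches raise :class:`DatasetFormatError` naming the discrepancy.
    """
    stack_path = Path(stack_path)
    meta_path = stack_path.with_suffix(".json") if meta_path is None else Path(meta_path)
    if not stack_path.exists():
        raise FileNotFoundError(stack_path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = json.loads(meta_path.read_text())
    if meta.get("schema") != SCHEMA:
        raise DatasetFormatError(f"unsupported schema {meta.get('schema')!r}, expected {SCHEMA!r}")
    if "pixel_pitch_mm" not in meta:
        raise DatasetFormatError("metadata missing pixel_pitch_mm")
    freqs = np.asarray(meta["frequencies_mm^-1"], dtype=float)
    phases = np.asarray(meta["phases_rad"], dtype=float)
    nf, nph = len(freqs), len(phases)
    pages = tifffile.imread(stack_path)
    if pages.ndim == 2:
        pages = pages[None]
    expected = nf * nph + nf
    if pages.shape[0] != expected:
        missing = [
            f"(f={freqs[i]:.4g}, theta={phases[j]:.4g})"
            for i in range(nf)
            for j in range(nph)
            if i * nph + j >= pages.shape[0]
        ]
        raise DatasetFormatError(
            f"stack has {pages.shape[0]} pages but metadata implies {expected} "
            f"({nf} frequencies x {nph} phases + {nf} bright-field); "
            + (f"missing fluorescence pages: {', '.join(missing)}" if missing else "extra pages")
        )
    ny, nx = pages.shape[1:]
    frames = np.empty((nf, nph, ny, nx), dtype=float)
    bright = np.empty((nf, ny, nx), dtype=float)
    for i in range(nf):
        for j in range(nph):
            frames[i, j] = pages[i * nph + j].astype(float)
        bright[i] = pages[nf * nph + i].astype(float)
    order = np.argsort(freqs)
    if not np.all(order == np.arange(nf)):
        log.warning("metadata frequencies unsorted; reordering ascending")
        freqs, frames, bright = freqs[order], frames[order], bright[order]
    return AcquisitionDataset(
        frequencies=freqs,
        phases=phases,
        frames=frames,
        brightfield=bright,
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        medium=_medium_from_dict(meta["medium"]),
        exposure=float(meta.get("exposure", 1.0)),
        provenance=meta.get("provenance", {}),
    )


def run_reconstruct(
    dataset: AcquisitionDataset,
    outdir: str | Path | None = None,
    medium: MediumPair | None = None,
    convention: str = "consistent",
    calibrate: bool = True,
    segment: bool = True,
    taper_fraction: float = 0.1,
    sigma_grid=None,
    true_area_mm2: float = 100.0,
) -> dict:
    """Drive the full pipeline and optionally write its artifacts.

    Runs demodulation, frequency calibration, optional lateral segmentation,
    the depth fit, sigma selection and margin reconstruction; returns a
    report dict (one entry per target plus the resolved parameters) and,
    when ``outdir`` is given, writes metrics.json, one 32-bit float TIFF
    concentration map and one FWHM-contour overlay PNG per target.
    """
    medium = medium or dataset.medium
    results = analyze_targets(
        dataset,
        medium,
        convention=convention,
        calibrate=calibrate,
        sigma_grid=sigma_grid,
        true_area_mm2=true_area_mm2,
        taper_fraction=taper_fraction,
        segment=segment,
    )
    i_dc = int(np.argmin(np.abs(dataset.frequencies)))
    dc = three_phase_demodulate(*dataset.triplet(i_dc), convention=convention)
    dc_int = np.clip(dc.real, 0.0, None)
    report = {
        "resolved": {
            "convention": convention,
            "calibrate": calibrate,
            "segment": segment,
            "taper_fraction": taper_fraction,
            "true_area_mm2": true_area_mm2,
            "medium": _medium_to_dict(medium),
            "n_frequencies": dataset.n_frequencies,
            "pixel_pitch_mm": dataset.pixel_pitch,
            "provenance": dataset.provenance,
        },
        "projection_relative_width": (
            projection_width(dc_int, dataset.pixel_pitch, true_area_mm2)
            if dc_int.max() > 0
            else None
        ),
        "targets": [r.metrics() for r in results],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "metrics.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        for idx, r in enumerate(results):
            if r.reconstruction is None:
                continue
            tifffile.imwrite(
                outdir / f"target{idx}_conc.tif",
                r.reconstruction.conc_map.astype(np.float32),
                photometric="minisblack",
            )
            _write_overlay(outdir / f"target{idx}_overlay.png", r.reconstruction, dataset.pixel_pitch)
    return report


def _write_overlay(path: Path, recon, pixel_pitch: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ny, nx = recon.conc_map.shape
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(
        recon.conc_map,
        extent=(0, nx * pixel_pitch, ny * pixel_pitch, 0),
        cmap="inferno",
    )
    for contour in recon.contours:
        ax.plot(contour[:, 1], contour[:, 0], color="cyan", lw=1.2)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"z = {recon.z_used:.2f} mm, sigma = {recon.sigma:.2f} mm$^{{-1}}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
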