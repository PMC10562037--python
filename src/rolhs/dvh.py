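"""Cumulative dose-volume histograms and summary metrics from dose grids.

Desk-scale stand-in for a DICOM-RT dosimetry parser: doses live on a small
3-D grid in cGy, structures are binary masks of the same shape.  The curve
reports, at uniform dose bin edges, the fraction of the structure's volume
receiving at least that dose.  Gy input is accepted with explicit conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rolhs.errors import ArgumentFailure, UndefinedMetricFailure

__all__ = ["DVHCurve", "compute_dvh", "dvh_metrics", "save_dose_grid",
           "load_dose_grid", "GY_TO_CGY"]

GY_TO_CGY = 100.0


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: volume fraction >= dose at each uniform bin edge."""

    edges: np.ndarray       # cGy, uniform width, starting at 0
    fractions: np.ndarray   # in [0, 1], non-increasing, fractions[0] == 1
    mean_dose: float        # from the underlying voxels
    n_voxels: int
    voxel_volume: float = 1.0
    voxel_doses: np.ndarray | None = None   # sorted; enables exact Dx/mean

    def __post_init__(self):
        if self.fractions[0] != 1.0:
            raise ArgumentFailure("DVH fraction at 0 cGy must be 1.0")
        if (np.diff(self.fractions) > 1e-12).any():
            raise ArgumentFailure("DVH must be monotone non-increasing")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["dose_cGy\tvolume_fraction"]
        lines += [f"{e:g}\t{f:.6f}" for e, f in zip(self.edges, self.fractions)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path


def compute_dvh(
    dose: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 50.0,
    voxel_volume: float = 1.0,
    dose_unit: str = "cGy",
) -> DVHCurve:
    """Cumulative DVH of the masked voxels at uniform ``bin_width`` edges.

    fraction(d) = #{voxels in mask with dose >= d} / #voxels in mask, with
    edges spanning 0 .. max dose + one bin.
    """
    if bin_width <= 0:
        raise ArgumentFailure("bin_width must be positive")
    dose = np.asarray(dose, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dose.shape != mask.shape:
        raise ArgumentFailure(
            f"mask shape {mask.shape} does not match dose grid {dose.shape}")
    if dose_unit == "Gy":
        dose = dose * GY_TO_CGY
    elif dose_unit != "cGy":
        raise ArgumentFailure(f"unknown dose unit {dose_unit!r}")
    if not mask.any():
        raise UndefinedMetricFailure("empty structure mask: DVH undefined")
    voxels = dose[mask]
    if (voxels < 0).any() or not np.all(np.isfinite(voxels)):
        raise ArgumentFailure("doses must be finite and non-negative")

    top = float(voxels.max())
    n_edges = int(np.floor(top / bin_width)) + 2  # spans 0..max + one bin
    edges = np.arange(n_edges) * bin_width
    ordered = np.sort(voxels)
    # voxels >= edge == n - (count of voxels strictly below edge)
    below = np.searchsorted(ordered, edges, side="left")
    fractions = (len(voxels) - below) / len(voxels)
    return DVHCurve(edges=edges, fractions=fractions,
                    mean_dose=float(voxels.mean()), n_voxels=int(len(voxels)),
                    voxel_volume=float(voxel_volume), voxel_doses=ordered)


def _interp_fraction(curve: DVHCurve, dose: float) -> float:
    if dose < 0 or dose > curve.edges[-1]:
        raise ArgumentFailure(
            f"dose {dose} outside curve domain [0, {curve.edges[-1]:g}]")
    return float(np.interp(dose, curve.edges, curve.fractions))


def dvh_metrics(curve: DVHCurve, requests: list[str]) -> dict[str, float]:
    """Evaluate requests like ``"D95"`` (cGy), ``"V2000"`` (%), ``"mean"``.

    Vx: volume percentage receiving at least x cGy, linearly interpolated
    between edges.  Dx: smallest dose (cGy) whose volume fraction is <= x/100,
    by inverse interpolation; ties take the smallest qualifying dose.
    ``mean`` comes from the underlying voxel doses.
    """
    out: dict[str, float] = {}
    for request in requests:
        name = request.strip()
        key = name.lower()
        if key == "mean":
            if np.isfinite(curve.mean_dose):
                out[name] = curve.mean_dose
            else:  # no voxel data: mean dose = integral of the survival curve
                out[name] = float(np.trapezoid(curve.fractions, curve.edges))
        elif key.startswith("v"):
            dose = float(name[1:].removesuffix("cGy").removesuffix("cgy"))
            out[name] = 100.0 * _interp_fraction(curve, dose)
        elif key.startswith("d"):
            target = float(name[1:]) / 100.0
            if not 0.0 <= target <= 1.0:
                raise ArgumentFailure(f"{name}: percentage outside [0, 100]")
            out[name] = _dose_at_fraction(curve, target)
        else:
            raise ArgumentFailure(f"unknown DVH metric request {request!r}")
    return out


def _dose_at_fraction(curve: DVHCurve, target: float) -> float:
    """Smallest dose whose volume fraction is <= target.

    With voxel doses available this is exact on the underlying step function:
    the smallest voxel value v with (n - count(doses <= v)) / n <= target
    (ties resolved to the smallest qualifying dose).  Without voxels, linear
    inverse interpolation of the binned curve.
    """
    if curve.voxel_doses is not None:
        doses = curve.voxel_doses  # sorted ascending
        n = len(doses)
        count_le = np.searchsorted(doses, doses, side="right")
        fraction_above = (n - count_le) / n
        qualifying = np.nonzero(fraction_above <= target)[0]
        if len(qualifying) == 0:
            raise ArgumentFailure(f"no dose with volume fraction <= {target}")
        return float(doses[qualifying[0]])
    fractions, edges = curve.fractions, curve.edges
    qualifying = np.nonzero(fractions <= target)[0]
    if len(qualifying) == 0:
        raise ArgumentFailure(f"no dose with volume fraction <= {target}")
    i = int(qualifying[0])
    if i == 0 or fractions[i] == target:
        while i > 0 and fractions[i - 1] == fractions[i]:
            i -= 1
        return float(edges[i])
    f_hi, f_lo = fractions[i - 1], fractions[i]
    w = (f_hi - target) / (f_hi - f_lo)
    return float(edges[i - 1] + w * (edges[i] - edges[i - 1]))


def save_dose_grid(path: str | Path, dose: np.ndarray,
                   masks: dict[str, np.ndarray], voxel_volume: float) -> Path:
    """Write dose + masks as a compressed .npz with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, dose=dose,
                        **{f"mask_{name}": mask for name, mask in masks.items()})
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "shape": list(dose.shape),
        "voxel_volume_cm3": voxel_volume,
        "structures": sorted(masks),
        "dose_unit": "cGy",
    }
    npz.with_suffix(".json").write_text(json.dumps(sidecar, indent=1),
                                        encoding="utf-8")
    return npz


def load_dose_grid(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """Inverse of :func:`save_dose_grid`; returns (dose, masks, voxel volume)."""
    path = Path(path)
    with np.load(path) as archive:
        dose = archive["dose"]
        masks = {key[5:]: archive[key].astype(bool)
                 for key in archive.files if key.startswith("mask_")}
    sidecar = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    if list(dose.shape) != sidecar["shape"]:
        raise ArgumentFailure("sidecar shape does not match dose array")
    return dose, masks, float(sidecar["voxel_volume_cm3"])
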