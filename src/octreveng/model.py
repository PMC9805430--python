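"""Top-level modelling interface: fit the whole pipeline, get results.

``GAProgressionModel`` wraps the full reverse-engineering pipeline --
label transfer, per-B-scan U-Net training under case-level
cross-validation, en-face evaluation -- behind a statsmodels-like
Model/Results pair:

    model = GAProgressionModel.from_phantoms(cases, config=cfg, k=4)
    res = model.fit(seed=0)
    print(res.summary())
    sal = res.reconstruct_case(0, bscan=12)   # deconvnet saliency

The Results object carries per-fold and combined metrics, per-case rows,
the trained fold networks and their loss histories, and exposes the
network-inversion reconstructions of held-out cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import evaluate as ev
from . import segnet
from .label_transform import (extrude_label, register_annotation,
                              resize_bilinear, resize_nearest)
from .phantom import PhantomCase
from .reconstruct import reconstruct_stack


def prepare_case(case: PhantomCase, in_shape=None,
                 case_id: str = "case") -> ev.PreparedCase:
    """Label transformation for one case: register the follow-up GA
    annotation into baseline coordinates, extrude it through the retina,
    and resample B-scans/masks to the network input shape."""
    h, w, d = case.oct.shape
    reg = register_annotation(case.followup_ga_mask, case.keypoints)
    truth_wd = resize_nearest(reg, (w, d))
    stack = extrude_label(truth_wd, case.layers.boundaries(), case.oct.shape)
    in_shape = tuple(in_shape) if in_shape is not None else (h, w)
    bscans, masks = [], []
    for k in range(d):
        b = case.oct[:, :, k]
        m = stack[:, :, k]
        if in_shape != (h, w):
            b = resize_bilinear(b, in_shape).astype(np.float32)
            m = resize_nearest(m, in_shape)
        bscans.append(np.asarray(b, dtype=np.float32))
        masks.append(m.astype(bool))
    return ev.PreparedCase(case_id=case_id, bscans=bscans, truth_masks=masks,
                           enface_truth=reg)


class GAProgressionModel:
    """GA-progression segmentation + reconstruction pipeline on a set of
    cases. ``config`` fixes the network architecture and training protocol;
    ``k`` the number of cross-validation folds."""

    def __init__(self, prepared_cases, config: segnet.UNetConfig | None = None,
                 k: int = 8, phantom_cases=None):
        self.cases = list(prepared_cases)
        if config is None:
            h, w = self.cases[0].bscans[0].shape
            config = segnet.UNetConfig(in_shape=(h, w))
        self.config = config
        self.k = k
        self.phantom_cases = phantom_cases

    @classmethod
    def from_phantoms(cls, cases, config: segnet.UNetConfig | None = None,
                      k: int = 8) -> "GAProgressionModel":
        in_shape = config.in_shape if config is not None else None
        prepared = [prepare_case(c, in_shape=in_shape, case_id=f"case_{i:03d}")
                    for i, c in enumerate(cases)]
        return cls(prepared, config=config, k=k, phantom_cases=list(cases))

    def fit(self, seed: int = 0, progress: bool = False) -> "GAProgressionResults":
        """Run the k-fold cross-validated pipeline and collect results."""
        cv = ev.crossvalidate(self.cases, self.config, k=self.k, seed=seed,
                              progress=progress)
        return GAProgressionResults(model=self, cv=cv, seed=seed)


@dataclass
class GAProgressionResults:
    model: GAProgressionModel
    cv: "ev.CrossValResult"
    seed: int

    # -- metric access ----------------------------------------------------
    @property
    def combined(self) -> ev.MetricsReport:
        return self.cv.combined

    @property
    def fold_results(self):
        return self.cv.fold_results

    def metrics_frame(self):
        return ev.metrics_table(self.cv.fold_results, self.cv.combined)

    def per_case_frame(self):
        import pandas as pd
        return pd.DataFrame(self.cv.per_case_rows)

    def summary(self) -> str:
        """Fold-by-fold metric table plus the combined row, as text."""
        df = self.metrics_frame()
        lines = ["GA progression segmentation, "
                 f"{self.model.k}-fold cross-validation "
                 f"({len(self.model.cases)} cases, seed {self.seed})",
                 "-" * 72,
                 df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
                 "-" * 72,
                 "overlap = TP/(TP+FP+FN) (Jaccard); tp_fraction = TP/total"]
        return "\n".join(lines)

    # -- models and reconstructions --------------------------------------
    def fold_of_case(self, case_index: int) -> int:
        for fr, idxs in zip(self.cv.fold_results, self.cv.folds):
            if case_index in idxs:
                return fr.fold_id
        raise KeyError(f"case {case_index} not in any fold")

    def heldout_model(self, case_index: int) -> segnet.UNetModel:
        """The network for which this case was held out (never trained on)."""
        return self.cv.models[self.fold_of_case(case_index)]

    def reconstruct_case(self, case_index: int, bscan: int):
        """Deconvnet reconstruction stack for one held-out B-scan."""
        m = self.heldout_model(case_index)
        return reconstruct_stack(m, self.model.cases[case_index].bscans[bscan])

    def lesion_energy_contrast(self):
        """Reconstruction-energy contrast on held-out converting lesions.

        For every converting (druse-cluster) lesion of every case, compare
        the mean absolute input-space reconstruction energy over the
        lesion's footprint columns against the same quantity over the
        non-converting (HRF/SDD) footprints of the same case, using the
        fold network that never saw the case. Returns a list of row dicts
        with a boolean ``contrast`` per lesion.
        """
        if self.model.phantom_cases is None:
            raise ValueError("phantom ground truth not attached; build the "
                             "model with from_phantoms()")
        rows = []
        for ci, (pcase, prep) in enumerate(zip(self.model.phantom_cases,
                                               self.model.cases)):
            rows.extend(lesion_energy_contrast(self.heldout_model(ci),
                                               pcase, prep))
        return rows


def lesion_energy_contrast(net, pcase: PhantomCase,
                           prep: ev.PreparedCase) -> list:
    """Per converting lesion of one case: is the deconvnet reconstruction
    energy inside its footprint higher than inside the non-converting
    (HRF/SDD) footprints of the same case?"""
    conv_fps = [l.enface_footprint for l in pcase.lesions if l.converts]
    nonconv = [l.enface_footprint for l in pcase.lesions if not l.converts]
    if not conv_fps or not nonconv:
        return []
    nonconv_union = np.logical_or.reduce(nonconv)
    energies = _column_energies(net, prep, conv_fps + [nonconv_union])
    e_non = energies[-1]
    return [{"case_id": prep.case_id, "lesion": li,
             "druse_energy": e_druse, "nonconverting_energy": e_non,
             "contrast": bool(e_druse > e_non)}
            for li, e_druse in enumerate(energies[:-1])]


def _column_energies(net, prep: ev.PreparedCase, footprints):
    """Mean |input-space reconstruction| per footprint.

    Footprints live on the volume (width, depth) grid; energies are taken
    over the corresponding network-resolution columns of each intersected
    B-scan.
    """
    w_vol = footprints[0].shape[0]
    d_vol = footprints[0].shape[1]
    w_net = prep.bscans[0].shape[1]
    needed = sorted({d for fp in footprints for d in np.unique(np.nonzero(fp)[1])})
    col_energy = {}
    for d in needed:
        stack = reconstruct_stack(net, prep.bscans[d])
        col_energy[d] = np.abs(stack.input_space).mean(axis=0)  # per column
    out = []
    for fp in footprints:
        vals = []
        for wv, dv in zip(*np.nonzero(fp)):
            wn = min(w_net - 1, int(wv * w_net / w_vol))
            vals.append(col_energy[dv][wn])
        out.append(float(np.mean(vals)) if vals else math.nan)
    return out
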