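"""PCA-based articulatable statistical shape model (Model / Results pair).

``ArticulatedShapeModel`` holds the training shape vectors; ``fit()``
performs the principal component analysis and returns
``ShapeModelResults`` carrying the mean shape, the orthonormal mode matrix
E, the mode standard deviations, and the intrinsic axis means.  New
instances are synthesized as

    s(b) = s_mean + E D b,          D = diag(sigma_1 ... sigma_m)

and a shape with the model's topology is projected onto the model by

    b = D^-1 E^+ (s - s_mean).

PCA is computed through the low-dimensional Gram matrix X^T X (an L x L
eigenproblem rather than a 3F x 3F one); its singular values give the mode
variances and the principal vectors are the data matrix times its singular
vectors, normalized.  Sample covariance uses the L-1 divisor.  An instance
is posed after synthesis by articulating with the instance's *own*
skeleton (the rotation axes and centres stored in the shape vector), so
joint spaces stay consistent as the shape changes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .limb import LimbModel, articulate, load_limb, save_limb
from .shape_vector import (ShapeVectorLayout, assemble_shape_vector,
                           disassemble_shape_vector)
from .sphere import intrinsic_mean

_DEGENERATE_REL_TOL = 1e-12


class ArticulatedShapeModel:
    """Statistical shape model of the multi-component limb.

    Parameters
    ----------
    vectors : (L, 3F) array or list of shape vectors
        Training shape vectors in the given layout.
    layout : ShapeVectorLayout
        Slice manifest anchored on the reference topology.
    mus : dict bone -> unit 3-vector
        Intrinsic means of the bone axis directions used by the log maps.
    """

    def __init__(self, vectors, layout: ShapeVectorLayout, mus: dict):
        X = np.atleast_2d(np.asarray(vectors, float))
        if X.shape[0] < 2:
            raise ValueError("need at least L = 2 training shapes")
        if X.shape[1] != layout.size:
            raise ValueError(f"shape vectors have length {X.shape[1]}, "
                             f"layout expects {layout.size}")
        self.vectors = X
        self.layout = layout
        self.mus = {k: np.asarray(v, float) for k, v in mus.items()}

    @classmethod
    def from_subjects(cls, subjects, reference: LimbModel,
                      layout: ShapeVectorLayout | None = None):
        """Build from normalized subjects (anything carrying ``components``
        on the reference topology and a ``skeleton``).  Intrinsic axis
        means are the Karcher means of the subjects' axis directions."""
        layout = layout or ShapeVectorLayout(reference)
        mus = {}
        for bid in layout.bone_order:
            axes = [s.skeleton.bones[bid].z_axis for s in subjects]
            mu, converged = intrinsic_mean(axes)
            if not converged:
                raise ValueError(f"axis directions of bone {bid!r} are not "
                                 "hemispherical; intrinsic mean undefined")
            mus[bid] = mu
        vectors = [assemble_shape_vector(s, layout, mus) for s in subjects]
        return cls(vectors, layout, mus)

    @property
    def n_subjects(self) -> int:
        return self.vectors.shape[0]

    def fit(self) -> "ShapeModelResults":
        """Run the PCA and return the fitted results."""
        X = self.vectors.T  # 3F x L, subjects in columns
        L = X.shape[1]
        mean = X.mean(axis=1)
        Xc = X - mean[:, None]
        G = Xc.T @ Xc  # L x L Gram matrix
        svals, V = np.linalg.eigh(G)
        order = np.argsort(svals)[::-1]
        svals = np.clip(svals[order], 0.0, None)
        V = V[:, order]
        m = min(L - 1, len(svals))
        svals = svals[:m]
        V = V[:, :m]
        E = Xc @ V
        norms = np.linalg.norm(E, axis=0)
        nonnull = norms > 0
        E[:, nonnull] /= norms[nonnull]
        # numerical hygiene: columns from near-null Gram eigenvalues are
        # noise and need not come out orthogonal; re-orthonormalize (the
        # genuine modes are already orthogonal, QR perturbs them at the
        # eigensolver's accuracy level)
        E, _ = np.linalg.qr(E)
        # deterministic eigenvector sign: largest-magnitude entry positive
        for k in range(E.shape[1]):
            j = int(np.argmax(np.abs(E[:, k])))
            if E[j, k] < 0:
                E[:, k] = -E[:, k]
        sigmas = np.sqrt(svals / (L - 1))
        return ShapeModelResults(self, mean, E, sigmas)


@dataclass
class ShapeModelResults:
    """Fitted articulatable SSM.

    Attributes
    ----------
    mean_ : (3F,) mean shape vector
    modes_ : (3F, m) orthonormal principal directions (columns)
    sigmas_ : (m,) mode standard deviations, descending
    """

    model: ArticulatedShapeModel
    mean_: np.ndarray
    modes_: np.ndarray
    sigmas_: np.ndarray

    @property
    def layout(self) -> ShapeVectorLayout:
        return self.model.layout

    @property
    def mus(self) -> dict:
        return self.model.mus

    @property
    def n_modes(self) -> int:
        return self.modes_.shape[1]

    @property
    def variances_(self) -> np.ndarray:
        return self.sigmas_ ** 2

    def _active(self) -> np.ndarray:
        """Indices of non-degenerate modes (sigma above relative floor)."""
        if len(self.sigmas_) == 0 or self.sigmas_[0] <= 0:
            return np.array([], dtype=int)
        return np.flatnonzero(self.sigmas_ > _DEGENERATE_REL_TOL * self.sigmas_[0])

    # -- synthesis and projection -------------------------------------
    def synthesize(self, b) -> np.ndarray:
        """s(b) = mean + E D b (b zero-padded/truncated to the mode count)."""
        b = np.atleast_1d(np.asarray(b, float))
        if len(b) < self.n_modes:
            b = np.pad(b, (0, self.n_modes - len(b)))
        b = b[: self.n_modes]
        return self.mean_ + self.modes_ @ (self.sigmas_ * b)

    def project(self, s, n_modes: int | None = None) -> np.ndarray:
        """Mode weights best approximating shape vector ``s``:
        b = D^-1 E^T (s - mean), restricted to non-degenerate modes (the
        orthonormal columns make the pseudo-inverse a transpose)."""
        s = np.asarray(s, float)
        resid = s - self.mean_
        b = np.zeros(self.n_modes)
        act = self._active()
        if n_modes is not None:
            act = act[act < n_modes]
        if len(act):
            b[act] = (self.modes_[:, act].T @ resid) / self.sigmas_[act]
        return b

    # statsmodels-flavoured alias
    fit_weights = project

    def sample(self, n: int, seed: int, n_modes: int | None = None):
        """Draw ``n`` instances with standard-normal mode weights (so mode
        i has standard deviation sigma_i in shape space).  Returns
        (vectors (n, 3F), weights (n, m))."""
        if n < 1:
            raise ValueError("need n >= 1 samples")
        rng = np.random.default_rng(seed)
        m = self.n_modes if n_modes is None else min(n_modes, self.n_modes)
        weights = np.zeros((n, self.n_modes))
        weights[:, :m] = rng.standard_normal((n, m))
        vectors = self.mean_[None, :] + (weights * self.sigmas_) @ self.modes_.T
        return vectors, weights

    # -- reconstruction ------------------------------------------------
    def instance(self, b, name: str = "instance") -> LimbModel:
        """Neutral-pose limb model for mode weights ``b``."""
        return disassemble_shape_vector(self.synthesize(b), self.layout, self.mus, name)

    def reconstruct_posed(self, b, joint_angles: dict[str, float],
                          name: str = "instance") -> LimbModel:
        """Synthesize an instance and articulate it with its own
        (b-dependent) skeleton."""
        limb = self.instance(b, name)
        return articulate(limb, joint_angles)

    # -- reporting ------------------------------------------------------
    def compactness(self) -> np.ndarray:
        """Cumulative explained variance, percent, per mode count."""
        total = self.variances_.sum()
        if total <= 0:
            raise ValueError("model has zero total variance")
        return 100.0 * np.cumsum(self.variances_) / total

    def summary(self) -> str:
        lines = [
            "Articulated statistical shape model",
            "=" * 51,
            f"training shapes (L):     {self.model.n_subjects}",
            f"shape vector length:     {len(self.mean_)}",
            f"components:              {len(self.layout.component_order)}",
            f"skeleton bones:          {self.layout.n_bones}",
            f"retained modes:          {self.n_modes}",
            "",
            f"{'mode':>4} {'sigma':>12} {'var %':>8} {'cum %':>8}",
        ]
        total = self.variances_.sum()
        cum = 0.0
        for i, s in enumerate(self.sigmas_):
            frac = 100.0 * s ** 2 / total if total > 0 else 0.0
            cum += frac
            lines.append(f"{i + 1:>4} {s:>12.5g} {frac:>8.2f} {cum:>8.2f}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str) -> None:
        """Archive: binary arrays + manifest + reference topology."""
        os.makedirs(directory, exist_ok=True)
        np.savez_compressed(
            os.path.join(directory, "arrays.npz"),
            mean=self.mean_, modes=self.modes_, sigmas=self.sigmas_,
            vectors=self.model.vectors,
            **{f"mu_{k}": v for k, v in self.mus.items()})
        manifest = {
            "component_order": self.layout.component_order,
            "bone_order": self.layout.bone_order,
            "y_hints": {k: v.tolist() for k, v in self.layout.y_hints.items()},
            "n_subjects": self.model.n_subjects,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        save_limb(self.layout.template, os.path.join(directory, "template"))

    @classmethod
    def load(cls, directory: str) -> "ShapeModelResults":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        template = load_limb(os.path.join(directory, "template"))
        data = np.load(os.path.join(directory, "arrays.npz"))
        layout = ShapeVectorLayout(
            template, manifest["component_order"], manifest["bone_order"],
            {k: np.asarray(v) for k, v in manifest["y_hints"].items()})
        mus = {k[3:]: data[k] for k in data.files if k.startswith("mu_")}
        model = ArticulatedShapeModel(data["vectors"], layout, mus)
        return cls(model, data["mean"], data["modes"], data["sigmas"])
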