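"""Linear-elastic finite-element model of a single vertebral body.

Model
-----
The cortical shell is discretised with plane-stress membrane triangles of
constant thickness t_c (the vertebra's Cr.Th) and fixed modulus E_cor; the
cancellous core with linear (constant-strain) tetrahedra of spatially
uniform modulus E_spong from the HU calibration chain.  Shell and core
share one node table, so they are rigidly bonded.  The intervertebral
disc below the body is an elastic bed of grounded springs on the inferior
contact nodes, each with stiffness

    k_i = E_iv * A_i / t_iv        (E_iv = 9.8 MPa, t_iv = 5 mm)

where A_i is the node's tributary area.  The axial load F (a level-
dependent fraction of body weight) acts along the load axis through the
centre of the superior contact surface and is spread over the superior
nodes by an RBE3-style interpolation: area-proportional force weights,
least-squares corrected so force and moment balance hold, adding no
stiffness to the system.

Usage follows the model/results idiom::

    model = VertebralFEModel(mesh, thickness_um, card, springs, load)
    res = model.fit()
    res.summary()

Units are mm / N / MPa throughout; shell thickness enters in µm and is
converted once at model build.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .materials import MaterialCard
from .meshing import FEMesh
from .specimens import SpineSpec, LEVELS

__all__ = [
    "GRAVITY",
    "SpringBed",
    "LoadCase",
    "FEAResults",
    "VertebralFEModel",
    "default_load_fractions",
    "level_load",
    "build_spring_bed",
    "rbe3_distribute",
    "stress_summaries",
    "failure_check",
    "solve_vertebra",
]

GRAVITY = 9.81  # m/s^2


# ---------------------------------------------------------------------------
# Loads


def default_load_fractions(levels: tuple[str, ...] = LEVELS) -> dict[str, float]:
    """Supported-body-mass fraction per level.

    A linear craniocaudal ramp from 0.08 at C3 to 0.60 at L5 — an explicit
    stand-in for the in-vivo segmental mass distribution, overridable in
    every entry point and flagged as an assumption in reports.
    """
    n = len(LEVELS)
    table = {}
    for lab in levels:
        i = LEVELS.index(lab)
        table[lab] = 0.08 + (0.60 - 0.08) * i / (n - 1)
    return table


def level_load(
    spine: SpineSpec, label: str, load_table: dict[str, float] | None = None
) -> float:
    """Axial force on one vertebra: F = fraction(level) · body mass · g, N."""
    spine[label]  # raises KeyError for unknown labels
    table = load_table if load_table is not None else default_load_fractions()
    fracs = [table[l] for l in LEVELS if l in table]
    if any(f2 < f1 for f1, f2 in zip(fracs, fracs[1:])):
        raise ValueError("load table must be nondecreasing craniocaudally")
    if not all(0 <= f <= 1 for f in fracs):
        raise ValueError("load fractions must lie in [0, 1]")
    return table[label] * spine.body_mass * GRAVITY


@dataclass
class SpringBed:
    """Grounded disc springs on the inferior contact nodes.

    ``stiffness`` holds k_i = E_iv·A_i/t_iv (N/mm) aligned with
    ``node_ids``.  The grounded end is fixed (zero displacement).  The bed
    acts isotropically (the disc also supports shear), which additionally
    removes the lateral rigid-body modes of the otherwise unconstrained
    body; the axial stiffness is exactly k_i.
    """

    node_ids: np.ndarray
    stiffness: np.ndarray  # N/mm per node
    e_iv: float = 9.8  # MPa
    t_iv: float = 5.0  # mm

    @property
    def total_stiffness(self) -> float:
        return float(self.stiffness.sum())


def contact_stiffness_shares(
    mesh: FEMesh, set_name: str, e_core: float, e_shell: float, t_shell_um: float
) -> np.ndarray:
    """Tributary axial-stiffness share of each contact node.

    s_i = E_spong·A_i + E_cor·t·l_i, with A_i the node's tributary area and
    l_i its tributary rim-perimeter length (nonzero only on the patch rim
    where the shell wall meets the endplate).  Used to couple loads and
    foundations compatibly with the composite cross-section, avoiding the
    Saint-Venant boundary layer a uniform-pressure coupling produces on a
    body shorter than its diameter.
    """
    areas = mesh.tributary_areas[set_name]
    perims = mesh.tributary_perimeters[set_name]
    return e_core * areas + e_shell * (t_shell_um / 1000.0) * perims


def build_spring_bed(
    mesh: FEMesh,
    e_iv: float = 9.8,
    t_iv: float = 5.0,
    apportion: np.ndarray | None = None,
) -> SpringBed:
    """Per-node axial springs k_i = e_iv·A_i/t_iv from tributary areas.

    With ``apportion`` (a per-node weight array, e.g. from
    :func:`contact_stiffness_shares`) the same total bed stiffness
    e_iv·A_total/t_iv is redistributed proportionally to the weights.
    """
    if "inferior_contact" not in mesh.node_sets:
        raise ValueError("mesh has no inferior_contact set; run tag_contact_surfaces")
    ids = mesh.node_sets["inferior_contact"]
    areas = mesh.tributary_areas["inferior_contact"]
    if areas.sum() <= 0:
        raise ValueError("inferior contact surface has zero area")
    if apportion is None:
        k = e_iv * areas / t_iv
    else:
        apportion = np.asarray(apportion, dtype=float)
        k = (e_iv * areas.sum() / t_iv) * apportion / apportion.sum()
    return SpringBed(node_ids=ids, stiffness=k, e_iv=e_iv, t_iv=t_iv)


@dataclass
class LoadCase:
    """Distributed axial load: master point on the load axis at the
    superior surface centroid, unit axis, total force (N) and per-node
    force weights over the superior contact set."""

    master_point: np.ndarray
    axis: np.ndarray
    force_f: float
    base_weights: np.ndarray | None = None  # pre-correction weights; default areas
    node_ids: np.ndarray = None
    weights: np.ndarray = None


def rbe3_distribute(mesh: FEMesh, load: LoadCase) -> np.ndarray:
    """Nodal force vector of an RBE3-style interpolation load.

    Weights start proportional to superior tributary areas (or to
    ``load.base_weights`` when given, e.g. axial-stiffness shares) and
    receive a minimum-norm correction enforcing Σw = 1 and zero first
    moment of the distributed forces about the master point perpendicular
    to the axis.  No stiffness is added to the system.  Returns the flat
    (3n,) force vector and stores the final weights on ``load``.
    """
    if "superior_contact" not in mesh.node_sets:
        raise ValueError("mesh has no superior_contact set; run tag_contact_surfaces")
    ids = mesh.node_sets["superior_contact"]
    areas = mesh.tributary_areas["superior_contact"]
    axis = np.asarray(load.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    base = areas if load.base_weights is None else np.asarray(load.base_weights, float)
    w0 = base / base.sum()
    d = mesh.nodes[ids] - np.asarray(load.master_point)[None, :]
    # two directions spanning the plane perpendicular to the axis
    t1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(t1) < 1e-8:
        t1 = np.cross(axis, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    C = np.stack([np.ones(len(ids)), d @ t1, d @ t2])
    b = np.array([1.0, 0.0, 0.0])
    gram = C @ C.T
    try:
        lam = np.linalg.solve(gram, b - C @ w0)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "rank-deficient RBE3 correction: superior contact nodes are "
            "collinear with the load axis"
        ) from exc
    w = w0 + C.T @ lam
    w = w / w.sum()
    load.node_ids = ids
    load.weights = w
    f = np.zeros((mesh.n_nodes, 3))
    f[ids] = np.outer(w * load.force_f, -axis)
    return f.ravel()


# ---------------------------------------------------------------------------
# Element stiffness (vectorised)


def _isotropic_d3(e: float, nu: float) -> np.ndarray:
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.diag_indices(3)] = lam + 2 * mu
    d[3, 3] = d[4, 4] = d[5, 5] = mu
    return d


def _plane_stress_d(e: float, nu: float) -> np.ndarray:
    c = e / (1 - nu**2)
    return c * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])


def _tet_b_matrices(nodes: np.ndarray, tets: np.ndarray):
    """Strain-displacement matrices (m, 6, 12) and volumes of linear tets."""
    p = nodes[tets]  # (m, 4, 3)
    j = p[:, 1:] - p[:, :1]  # (m, 3, 3)
    vol = np.linalg.det(j) / 6.0
    jinv = np.linalg.inv(j)  # rows of jinv.T are grads of N1..N3
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:] = np.transpose(jinv, (0, 2, 1))
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    m = len(tets)
    b = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        b[:, 0, c] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c] = gy
        b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz
        b[:, 4, c + 2] = gy
        b[:, 5, c] = gz
        b[:, 5, c + 2] = gx
    return b, vol


def _membrane_element_data(nodes: np.ndarray, tris: np.ndarray):
    """Local frames, 2-D coordinates, B matrices (s, 3, 6) and areas."""
    p = nodes[tris]  # (s, 3, 3)
    e1 = p[:, 1] - p[:, 0]
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(nrm, axis=1)
    nrm_unit = nrm / (2 * area[:, None])
    e2 = np.cross(nrm_unit, e1)
    # 2-D coordinates in the element plane
    q = np.empty((len(tris), 3, 2))
    for a in range(3):
        rel = p[:, a] - p[:, 0]
        q[:, a, 0] = np.einsum("ij,ij->i", rel, e1)
        q[:, a, 1] = np.einsum("ij,ij->i", rel, e2)
    x, y = q[..., 0], q[..., 1]
    b = np.zeros((len(tris), 3, 6))
    idx = [(1, 2), (2, 0), (0, 1)]
    for a, (m_, n_) in enumerate(idx):
        beta = y[:, m_] - y[:, n_]
        gamma = x[:, n_] - x[:, m_]
        c = 2 * a
        b[:, 0, c] = beta
        b[:, 1, c + 1] = gamma
        b[:, 2, c] = gamma
        b[:, 2, c + 1] = beta
    b /= (2 * area)[:, None, None]
    frames = np.stack([e1, e2], axis=1)  # (s, 2, 3)
    return frames, b, area


def _scatter(ke: np.ndarray, conn: np.ndarray, ndof_per_node: int, dofs_total: int):
    """COO triplets for a batch of element stiffness matrices."""
    m, edof, _ = ke.shape
    dof = (conn[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(m, edof)
    rows = np.repeat(dof, edof, axis=1).ravel()
    cols = np.tile(dof, (1, edof)).ravel()
    return rows, cols, ke.ravel()


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class FEAResults:
    """Solution of one vertebral FE model.

    Per-element von Mises stresses are split by compartment (shell =
    cortical, tets = cancellous).  Summaries are recomputable from the
    element arrays via :meth:`summaries`.
    """

    model: "VertebralFEModel"
    displacements: np.ndarray  # (n, 3) mm
    shell_von_mises: np.ndarray  # (s,) MPa
    tet_von_mises: np.ndarray  # (m,) MPa
    spring_reactions: np.ndarray  # (k, 3) N

    # -- summaries ----------------------------------------------------------

    def deflection(self, mode: str = "axial") -> float:
        """Maximal displacement of the body along the load axis (mm);
        ``mode='magnitude'`` uses the full displacement norm instead."""
        if mode == "axial":
            axial = self.displacements @ self.model.load.axis
            return float(np.abs(axial).max())
        if mode == "magnitude":
            return float(np.linalg.norm(self.displacements, axis=1).max())
        raise ValueError(f"unknown deflection mode {mode!r}")

    def summaries(self, percentile: float = 100.0, deflection_mode: str = "axial") -> dict:
        return {
            "cortical_stress": float(np.percentile(self.shell_von_mises, percentile)),
            "cancellous_stress": float(np.percentile(self.tet_von_mises, percentile)),
            "deflection": self.deflection(deflection_mode),
            "percentile": percentile,
        }

    def failure_margin(self) -> float:
        return float(self.tet_von_mises.max() / self.model.material.s_max_spong)

    @property
    def predicts_failure(self) -> bool:
        return self.failure_margin() >= 1.0  # boundary inclusive

    def reaction_sum(self) -> np.ndarray:
        return self.spring_reactions.sum(axis=0)

    def summary(self, percentile: float = 100.0) -> str:
        m = self.model
        s = self.summaries(percentile)
        lines = [
            "Vertebral body FE results" + (f" — {m.label}" if m.label else ""),
            "=" * 48,
            f"nodes {m.mesh.n_nodes}   tets {len(m.mesh.tetrahedra)}   "
            f"shell tris {len(m.mesh.shell_triangles)}",
            f"E_cor {m.material.e_cor:.6g} MPa   E_spong {m.material.e_spong:.6g} MPa   "
            f"nu {m.nu}",
            f"shell thickness {m.thickness_um:.6g} µm   axial load {m.load.force_f:.6g} N",
            f"spring bed: {len(m.springs.node_ids)} nodes, "
            f"total {m.springs.total_stiffness:.6g} N/mm",
            "-" * 48,
            f"cortical von Mises (p{percentile:g})   {s['cortical_stress']:.4g} MPa",
            f"cancellous von Mises (p{percentile:g}) {s['cancellous_stress']:.4g} MPa",
            f"deflection (max axial)          {s['deflection']:.4g} mm",
            f"failure margin (max/S_max)      {self.failure_margin():.4g}"
            + ("  ** failure predicted **" if self.predicts_failure else ""),
        ]
        return "\n".join(lines)

    def to_vtk(self, path) -> None:
        from .meshing import write_vtk

        write_vtk(
            path,
            self.model.mesh,
            point_data={"displacement": self.displacements},
            cell_data={"cancellous_von_mises": self.tet_von_mises},
        )


class VertebralFEModel:
    """Membrane-shell + tet-core model of one vertebral body.

    Parameters
    ----------
    mesh : FEMesh with tagged contact sets.
    thickness_um : cortical shell thickness (µm, converted to mm once).
    material : MaterialCard with e_cor / e_spong / s_max_spong (MPa).
    springs : SpringBed on the inferior contact nodes.
    load : LoadCase (master point, axis, total force).
    nu : Poisson ratio for both compartments (source silent; default 0.3).
    """

    def __init__(
        self,
        mesh: FEMesh,
        thickness_um: float,
        material: MaterialCard,
        springs: SpringBed,
        load: LoadCase,
        nu: float = 0.3,
        label: str = "",
    ) -> None:
        if thickness_um <= 0:
            raise ValueError("shell thickness must be positive")
        if material.e_cor <= 0 or material.e_spong <= 0:
            raise ValueError("moduli must be positive")
        self.mesh = mesh
        self.thickness_um = float(thickness_um)
        self.material = material
        self.springs = springs
        self.load = load
        self.nu = float(nu)
        self.label = label or getattr(material, "vertebra_label", "")
        self._cache: dict = {}

    @classmethod
    def from_spec(
        cls,
        spec,
        material: MaterialCard,
        force: float,
        edge_target: float = 2.0,
        nu: float = 0.3,
        thickness_um: float | None = None,
        e_iv: float = 9.8,
        t_iv: float = 5.0,
        coupling: str = "stiffness",
    ) -> "VertebralFEModel":
        """Build mesh, springs and load case directly from a VertebraSpec.

        ``coupling`` selects how the end load and the disc bed are
        apportioned over contact nodes: ``"stiffness"`` (default) weights
        them by tributary axial stiffness so the load enters the shell and
        core compatibly with the composite cross-section — the regime the
        adjacent, much stiffer vertebral body enforces — while ``"area"``
        applies uniform pressure (a fluid-like disc nucleus).  Uniform
        pressure on a body shorter than its diameter leaves a Saint-Venant
        layer in which the core sees ~F/A regardless of its stiffness.
        """
        from .meshing import tag_contact_surfaces, tetrahedralize
        from .specimens import vertebra_surface

        if coupling not in ("stiffness", "area"):
            raise ValueError(f"unknown coupling {coupling!r}")
        surface = vertebra_surface(spec, edge_target)
        mesh = tetrahedralize(surface)
        tag_contact_surfaces(mesh, (0.0, 0.0, 1.0))
        t_um = thickness_um if thickness_um is not None else spec.cortical_thickness
        apportion = None
        base_weights = None
        if coupling == "stiffness":
            apportion = contact_stiffness_shares(
                mesh, "inferior_contact", material.e_spong, material.e_cor, t_um
            )
            base_weights = contact_stiffness_shares(
                mesh, "superior_contact", material.e_spong, material.e_cor, t_um
            )
        springs = build_spring_bed(mesh, e_iv=e_iv, t_iv=t_iv, apportion=apportion)
        sup = mesh.node_sets["superior_contact"]
        areas = mesh.tributary_areas["superior_contact"]
        centroid = (mesh.nodes[sup] * areas[:, None]).sum(axis=0) / areas.sum()
        load = LoadCase(
            master_point=centroid,
            axis=np.array([0.0, 0.0, 1.0]),
            force_f=float(force),
            base_weights=base_weights,
        )
        return cls(mesh, t_um, material, springs, load, nu=nu, label=spec.label)

    # -- assembly -----------------------------------------------------------

    def _assemble(self):
        mesh = self.mesh
        n = mesh.n_nodes
        ndof = 3 * n
        d3 = _isotropic_d3(self.material.e_spong, self.nu)
        b_tet, vol = _tet_b_matrices(mesh.nodes, mesh.tetrahedra)
        if np.any(vol <= 0):
            raise ValueError("non-positive tetrahedron volume")
        ke_tet = np.einsum("mia,ij,mjb,m->mab", b_tet, d3, b_tet, vol)
        rows_t, cols_t, vals_t = _scatter(ke_tet, mesh.tetrahedra, 3, ndof)

        dps = _plane_stress_d(self.material.e_cor, self.nu)
        frames, b_mem, area = _membrane_element_data(mesh.nodes, mesh.shell_triangles)
        t_mm = self.thickness_um / 1000.0
        k2 = np.einsum("sia,ij,sjb,s->sab", b_mem, dps, b_mem, t_mm * area)
        # expand local 6x6 to global 9x9 through the 2x3 frame per node pair
        s = len(mesh.shell_triangles)
        k9 = np.zeros((s, 9, 9))
        for a in range(3):
            for bb in range(3):
                blk = k2[:, 2 * a : 2 * a + 2, 2 * bb : 2 * bb + 2]
                k9[:, 3 * a : 3 * a + 3, 3 * bb : 3 * bb + 3] = np.einsum(
                    "spi,spq,sqj->sij", frames, blk, frames
                )
        rows_s, cols_s, vals_s = _scatter(k9, mesh.shell_triangles, 3, ndof)

        ids = self.springs.node_ids
        kdiag = np.repeat(self.springs.stiffness, 3)
        dof_spring = (ids[:, None] * 3 + np.arange(3)[None, :]).ravel()

        k = sparse.coo_matrix(
            (
                np.concatenate([vals_t, vals_s, kdiag]),
                (
                    np.concatenate([rows_t, rows_s, dof_spring]),
                    np.concatenate([cols_t, cols_s, dof_spring]),
                ),
            ),
            shape=(ndof, ndof),
        ).tocsc()
        self._cache.update(
            b_tet=b_tet, d3=d3, b_mem=b_mem, dps=dps, frames=frames, k=k
        )
        return k

    def fit(self) -> FEAResults:
        """Assemble and solve K u = f; extract per-element von Mises."""
        k = self._cache.get("k")
        if k is None:
            k = self._assemble()
        f = rbe3_distribute(self.mesh, self.load)
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            u = spsolve(k, f)
        f_norm = np.linalg.norm(f)
        residual = np.linalg.norm(k @ u - f) / max(f_norm, 1e-30)
        if not np.all(np.isfinite(u)) or (f_norm > 0 and residual > 1e-6):
            raise RuntimeError(
                "singular stiffness matrix: check the spring bed and contact "
                "sets constrain all rigid-body modes"
            )
        u3 = u.reshape(-1, 3)
        # cancellous element stresses
        b_tet, d3 = self._cache["b_tet"], self._cache["d3"]
        ue_t = u3[self.mesh.tetrahedra].reshape(len(self.mesh.tetrahedra), 12)
        sig_t = np.einsum("ij,mja,ma->mi", d3, b_tet, ue_t)
        tet_vm = _von_mises_3d(sig_t)
        # cortical membrane stresses in local frames
        b_mem, dps, frames = (
            self._cache["b_mem"],
            self._cache["dps"],
            self._cache["frames"],
        )
        tris = self.mesh.shell_triangles
        u_tri = u3[tris]  # (s, 3, 3)
        u_loc = np.einsum("spi,sai->sap", frames, u_tri).reshape(len(tris), 6)
        sig_m = np.einsum("ij,sja,sa->si", dps, b_mem, u_loc)
        shell_vm = np.sqrt(
            sig_m[:, 0] ** 2
            - sig_m[:, 0] * sig_m[:, 1]
            + sig_m[:, 1] ** 2
            + 3 * sig_m[:, 2] ** 2
        )
        reactions = -self.springs.stiffness[:, None] * u3[self.springs.node_ids]
        return FEAResults(
            model=self,
            displacements=u3,
            shell_von_mises=shell_vm,
            tet_von_mises=tet_vm,
            spring_reactions=reactions,
        )


def _von_mises_3d(sig: np.ndarray) -> np.ndarray:
    sx, sy, sz, txy, tyz, tzx = sig.T
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )


# ---------------------------------------------------------------------------
# Free-function result post-processing (thin wrappers over FEAResults)


def stress_summaries(result: FEAResults, percentile: float = 100.0) -> dict:
    """Per-vertebra scalars: chosen percentile of shell / tet von Mises and
    the maximal axial deflection."""
    return result.summaries(percentile=percentile)


def failure_check(result: FEAResults, card: MaterialCard | None = None) -> dict:
    """Failure margin = max cancellous von Mises / S_max,spong; a margin of
    one or more predicts fracture (boundary inclusive)."""
    s_max = (card or result.model.material).s_max_spong
    margin = float(result.tet_von_mises.max() / s_max)
    return {"margin": margin, "failure": margin >= 1.0}


def solve_vertebra(
    spec,
    material: MaterialCard,
    force: float,
    edge_target: float = 2.0,
    nu: float = 0.3,
    thickness_um: float | None = None,
    coupling: str = "stiffness",
) -> FEAResults:
    """Convenience: build the model from a VertebraSpec and fit it."""
    model = VertebralFEModel.from_spec(
        spec,
        material,
        force,
        edge_target=edge_target,
        nu=nu,
        thickness_um=thickness_um,
        coupling=coupling,
    )
    return model.fit()
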