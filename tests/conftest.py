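import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=RuntimeWarning)

from valvetrack.mesh import TriangleSurfaceMesh
from valvetrack.phantom import (DeformationSpec, ImageSynthesisSpec,
                                ValveShapeParams, apply_analytic_deformation,
                                generate_valve_surface, synthesize_volumes)


@pytest.fixture(scope="session")
def trileaflet():
    """Default trileaflet phantom at working resolution."""
    return generate_valve_surface(ValveShapeParams(target_edge=0.8, seed=1))


@pytest.fixture(scope="session")
def trileaflet_fine():
    return generate_valve_surface(ValveShapeParams(target_edge=0.5, seed=4))


@pytest.fixture(scope="session")
def billow_spec():
    """Strain-realistic closure map (amplitudes within reported
    physiological strain ranges)."""
    return DeformationSpec(kind="closure_billow", amplitude=3.0,
                           axial_drop=1.0, height_ref=9.0, radius_ref=24.0)


@pytest.fixture(scope="session")
def closure_pair(trileaflet, billow_spec):
    closed = apply_analytic_deformation(trileaflet, billow_spec)
    return trileaflet, closed


@pytest.fixture(scope="session")
def phantom_images(closure_pair):
    mesh, closed = closure_pair
    return synthesize_volumes(mesh, closed,
                              ImageSynthesisSpec(seed=1))


@pytest.fixture(scope="session")
def known_warp_pair(closure_pair):
    """TEE-like grayscale frame and a smooth synthetically warped copy
    with the exact pull-back map known in closed form."""
    from scipy import ndimage
    mesh, closed = closure_pair
    g = synthesize_volumes(mesh, closed,
                           ImageSynthesisSpec.tee_preset(seed=1)).gray_open
    c = g.index_to_world((np.array(g.shape) - 1) / 2.0) + [3.0, 2.0, 1.0]

    def truth(pts):
        d = pts - c
        w = np.exp(-np.sum(d * d, axis=1) / (2 * 6.0 ** 2))
        return pts + np.array([1.2, -0.9, 0.8]) * w[:, None]

    idx = np.indices(g.shape).reshape(3, -1).T
    pts = g.index_to_world(idx)
    mi = g.world_to_index(truth(pts)).T
    warped = ndimage.map_coordinates(np.asarray(g.values, float), mi,
                                     order=1).reshape(g.shape)
    return g.like(warped), g, truth


@pytest.fixture(scope="session")
def known_warp_dense_ssd(known_warp_pair):
    """SSD deformable registration of the grayscale known-warp pair
    (shared by composition/warping machinery tests)."""
    from valvetrack.registration import (RegistrationSchedule,
                                         deformable_register)
    fixed, moving, truth = known_warp_pair
    return deformable_register(fixed, moving,
                               sched=RegistrationSchedule(metric="SSD"))


@pytest.fixture(scope="session")
def known_warp_dense_ncc(known_warp_pair):
    """NCC deformable registration of the grayscale known-warp pair
    (the metric the method uses for grayscale images)."""
    from valvetrack.registration import (RegistrationSchedule,
                                         deformable_register)
    fixed, moving, truth = known_warp_pair
    return deformable_register(fixed, moving,
                               sched=RegistrationSchedule(metric="NCC"))


@pytest.fixture(scope="session")
def known_warp_binary_pair(closure_pair, known_warp_pair):
    """Binary segmentation frame warped by the same closed-form map
    (the image class the method registers with SSD)."""
    from scipy import ndimage
    mesh, closed = closure_pair
    _, gray, truth = known_warp_pair
    lab = synthesize_volumes(mesh, closed,
                             ImageSynthesisSpec.tee_preset(seed=1)
                             ).labels_open
    binary = (np.asarray(lab.values) > 0).astype(np.float64)
    idx = np.indices(lab.shape).reshape(3, -1).T
    pts = lab.index_to_world(idx)
    mi = lab.world_to_index(truth(pts)).T
    warped = ndimage.map_coordinates(binary, mi, order=1).reshape(lab.shape)
    return lab.like(warped, kind="grayscale"), \
        lab.like(binary, kind="grayscale"), truth


@pytest.fixture(scope="session")
def zero_motion_case():
    from valvetrack.pipeline import CaseInput, make_phantom_case
    case, _, _ = make_phantom_case(seed=11)
    return CaseInput(gray_open=case.gray_open, gray_closed=case.gray_open,
                     seg_open=case.seg_open,
                     seg_closed_truth=case.seg_open,
                     medial_mesh=case.medial_mesh, name="static")


@pytest.fixture(scope="session")
def zero_motion_results(zero_motion_case):
    from valvetrack.pipeline import run_direct, run_fem_augmented
    direct = run_direct(zero_motion_case)
    augmented = run_fem_augmented(zero_motion_case, direct_result=direct)
    return direct, augmented


@pytest.fixture(scope="session")
def translated_pair():
    """Phantom and a rigidly translated copy rasterized on one grid."""
    m = generate_valve_surface(ValveShapeParams(target_edge=0.8, seed=1))
    shift = np.array([3.0, -2.0, 1.5])
    mt = m.with_vertices(m.vertices + shift)
    imgs = synthesize_volumes(m, mt, ImageSynthesisSpec(
        seed=1, extent=(72, 72, 72)))
    return m, shift, imgs


@pytest.fixture(scope="session")
def translation_affine_ncc(translated_pair):
    from valvetrack.registration import (RegistrationSchedule,
                                         affine_register)
    m, shift, imgs = translated_pair
    return affine_register(imgs.gray_open, imgs.gray_closed,
                           RegistrationSchedule(metric="NCC"))


@pytest.fixture(scope="session")
def convergence_table(trileaflet):
    """Mesh-refinement study of the pressurized closure (shared by the
    solver tests and the acceptance suite)."""
    from valvetrack.constitutive import MaterialParams
    from valvetrack.fe import MMHG_TO_KPA, LoadCase, mesh_convergence_study
    lc = LoadCase(pressure=75 * MMHG_TO_KPA,
                  annulus_displacement=np.zeros(
                      (len(trileaflet.annulus_nodes), 3)))
    return mesh_convergence_study(trileaflet, MaterialParams(), lc,
                                  [0.8, 0.6, 0.4], n_steps=10,
                                  bending_stiffness=5.0)


@pytest.fixture(scope="session")
def e2e_suite():
    """Five seeded closure phantoms tracked with both methods."""
    from valvetrack.pipeline import (make_phantom_case, run_direct,
                                     run_fem_augmented)
    rows = []
    for seed in (1, 2, 3, 4, 5):
        case, closed_truth, closure = make_phantom_case(seed=seed)
        direct = run_direct(case)
        augmented = run_fem_augmented(case, direct_result=direct)
        rows.append({"seed": seed, "direct": direct, "augmented": augmented})
    return rows


@pytest.fixture(scope="session")
def affine_closure_result():
    """Full pipeline run on a phantom whose ground-truth closure is an
    affine contraction (analytic strain known exactly)."""
    from valvetrack.pipeline import CaseInput, run_fem_augmented
    # an expansive map: a membrane can sustain prescribed boundary
    # tension (a compressive one buckles out of plane instead of
    # carrying in-plane compression, and in-plane contraction of a
    # thin shell is invisible to image registration)
    shape = ValveShapeParams(target_edge=0.8, seed=21)
    mesh = generate_valve_surface(shape)
    spec = DeformationSpec(kind="uniform_scale", scale=1.08)
    spec = spec.resolved_for(mesh)
    closed = apply_analytic_deformation(mesh, spec)
    imgs = synthesize_volumes(mesh, closed,
                              ImageSynthesisSpec.ct_preset(seed=21))
    case = CaseInput(gray_open=imgs.gray_open, gray_closed=imgs.gray_closed,
                     seg_open=imgs.labels_open,
                     seg_closed_truth=imgs.labels_closed,
                     medial_mesh=mesh, name="affine")
    return run_fem_augmented(case), spec


@pytest.fixture(scope="session")
def flat_sheet():
    """Flat square membrane sheet with a clamped rim node set."""
    nx = 9
    xs, ys = np.meshgrid(np.linspace(0, 10, nx), np.linspace(0, 10, nx),
                         indexing="ij")
    verts = np.stack([xs.ravel(), ys.ravel(), np.zeros(nx * nx)], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(nx - 1):
            a = i * nx + j
            b = (i + 1) * nx + j
            c = (i + 1) * nx + j + 1
            d = i * nx + j + 1
            faces += [(a, b, c), (a, c, d)]
    rim = np.where((verts[:, 0] < 1e-9) | (verts[:, 0] > 10 - 1e-9)
                   | (verts[:, 1] < 1e-9) | (verts[:, 1] > 10 - 1e-9))[0]
    return TriangleSurfaceMesh(verts, np.array(faces), annulus_nodes=rim,
                               thickness=1.2)
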