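"""Shared fixtures: session-scoped Monte Carlo kernels and small phantoms.

Kernel simulations are the expensive ingredient, so the homogeneous-medium
kernels used across several test modules are built once per session at a
moderate history count.
"""

import numpy as np
import pytest

from voxdose.kernels import (KernelLibrary, build_homogeneous_kernel,
                             homogeneous_patch)
from voxdose.phantoms import (CORTICAL_BONE, LUNG, SOFT_TISSUE,
                              TRABECULAR_BONE, PhantomSpec, generate_phantom)

KERNEL_HISTORIES = 100_000
KERNEL_SEED = 5


@pytest.fixture(scope="session")
def soft_kernel():
    """Homogeneous soft-tissue kernel (infinite medium, 1e5 histories)."""
    return build_homogeneous_kernel(SOFT_TISSUE, KERNEL_HISTORIES,
                                    KERNEL_SEED)


@pytest.fixture(scope="session")
def lung_kernel():
    return build_homogeneous_kernel(LUNG, KERNEL_HISTORIES, KERNEL_SEED)


@pytest.fixture(scope="session")
def trabecular_kernel():
    return build_homogeneous_kernel(TRABECULAR_BONE, KERNEL_HISTORIES,
                                    KERNEL_SEED)


@pytest.fixture(scope="session")
def cortical_kernel():
    return build_homogeneous_kernel(CORTICAL_BONE, KERNEL_HISTORIES,
                                    KERNEL_SEED)


@pytest.fixture(scope="session")
def msv_library(soft_kernel, lung_kernel, trabecular_kernel, cortical_kernel):
    return KernelLibrary({SOFT_TISSUE: soft_kernel, LUNG: lung_kernel,
                          TRABECULAR_BONE: trabecular_kernel,
                          CORTICAL_BONE: cortical_kernel},
                         histories=KERNEL_HISTORIES, seed=KERNEL_SEED)


@pytest.fixture(scope="session")
def small_torso():
    """32^3 torso phantom (density, materials) with lungs and spine."""
    spec = PhantomSpec.default_torso((32, 32, 32))
    return generate_phantom(spec, seed=7)


@pytest.fixture(scope="session")
def soft_patch():
    return homogeneous_patch(SOFT_TISSUE)


@pytest.fixture(scope="session")
def lung_patch():
    return homogeneous_patch(LUNG)
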