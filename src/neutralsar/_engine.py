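"""Event-driven core of the community simulator (numba-compiled).

The process is simulated exactly in continuous time: the next event time is
exponential with the total rate, the event type is chosen in proportion to the
rates, and the affected individual uniformly.  Randomness comes from an inline
xoshiro256++ generator seeded through splitmix64, so identical seeds give
bit-identical trajectories independent of platform or numpy version.
"""
from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64


@njit(cache=True, inline="always")
def _rotl(x, k):
    return U64((x << U64(k)) | (x >> U64(64 - k)))


@njit(cache=True)
def seed_state(seed):
    """Expand a nonnegative integer seed into xoshiro256 state via splitmix64."""
    s = np.empty(4, dtype=np.uint64)
    z = U64(seed)
    for i in range(4):
        z = U64(z + U64(0x9E3779B97F4A7C15))
        t = z
        t = U64((t ^ (t >> U64(30))) * U64(0xBF58476D1CE4E5B9))
        t = U64((t ^ (t >> U64(27))) * U64(0x94D049BB133111EB))
        s[i] = U64(t ^ (t >> U64(31)))
    return s


@njit(cache=True, inline="always")
def _next_u64(s):
    result = U64(_rotl(U64(s[0] + s[3]), 23) + s[0])
    t = U64(s[1] << U64(17))
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], 45)
    return result


@njit(cache=True, inline="always")
def _next_double(s):
    return (_next_u64(s) >> U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _next_below(s, n):
    # modulo bias is < n / 2^64, irrelevant for n << 2^64
    return int(_next_u64(s) % U64(n))


@njit(cache=True)
def run_events(state, x, y, species, n0, next_species0, L, b, d, spec_rate,
               t0, t_end, cap, kernel_kind, sigma_axis, lattice_dx, self_prob):
    """Advance the community from time t0 to t_end in place.

    kernel_kind: 0 = isotropic Gaussian (per-axis std sigma_axis),
                 1 = lattice nearest-neighbour (stay with self_prob, else one
                     of the 4 neighbours at spacing lattice_dx).

    Returns (n, t, births, deaths, speciations, next_species, hit_cap).
    """
    n = n0
    t = t0
    births = 0
    deaths = 0
    speciations = 0
    next_species = next_species0
    two_pi = 2.0 * np.pi
    while True:
        tot = n * (b + d) + spec_rate
        u = _next_double(state)
        while u <= 0.0:
            u = _next_double(state)
        t += -np.log(u) / tot
        if t >= t_end:
            t = t_end
            break
        ev = _next_double(state) * tot
        if ev < n * d:
            i = _next_below(state, n)
            n -= 1
            x[i] = x[n]
            y[i] = y[n]
            species[i] = species[n]
            deaths += 1
        elif ev < n * (b + d):
            i = _next_below(state, n)
            if kernel_kind == 0:
                u1 = _next_double(state)
                while u1 <= 0.0:
                    u1 = _next_double(state)
                u2 = _next_double(state)
                rr = np.sqrt(-2.0 * np.log(u1)) * sigma_axis
                dx = rr * np.cos(two_pi * u2)
                dy = rr * np.sin(two_pi * u2)
            else:
                w = _next_double(state)
                if w < self_prob:
                    dx = 0.0
                    dy = 0.0
                else:
                    k = _next_below(state, 4)
                    if k == 0:
                        dx = lattice_dx
                        dy = 0.0
                    elif k == 1:
                        dx = -lattice_dx
                        dy = 0.0
                    elif k == 2:
                        dx = 0.0
                        dy = lattice_dx
                    else:
                        dx = 0.0
                        dy = -lattice_dx
            if n >= cap:
                return n, t, births, deaths, speciations, next_species, True
            x[n] = (x[i] + dx) % L
            y[n] = (y[i] + dy) % L
            species[n] = species[i]
            n += 1
            births += 1
        else:
            if n >= cap:
                return n, t, births, deaths, speciations, next_species, True
            x[n] = _next_double(state) * L
            y[n] = _next_double(state) * L
            species[n] = next_species
            next_species += 1
            n += 1
            speciations += 1
    return n, t, births, deaths, speciations, next_species, False


@njit(cache=True)
def torus_dist2(x0, y0, x, y, L):
    """Squared toroidal distances from (x0, y0) to each point."""
    out = np.empty(x.size)
    half = L / 2.0
    for i in range(x.size):
        dx = abs(x[i] - x0)
        if dx > half:
            dx = L - dx
        dy = abs(y[i] - y0)
        if dy > half:
            dy = L - dy
        out[i] = dx * dx + dy * dy
    return out


@njit(cache=True)
def sample_pairs(state, x, y, species, L, edges2, max_pairs, attempts):
    """Sample random unordered pairs, bin by squared toroidal distance.

    edges2: squared bin edges, increasing. Each bin accepts at most max_pairs
    pairs. Returns (conspecific counts, total counts) per bin.
    """
    nbins = edges2.size - 1
    same = np.zeros(nbins, dtype=np.int64)
    tot = np.zeros(nbins, dtype=np.int64)
    n = x.size
    half = L / 2.0
    for _ in range(attempts):
        i = _next_below(state, n)
        j = _next_below(state, n)
        if i == j:
            continue
        dx = abs(x[i] - x[j])
        if dx > half:
            dx = L - dx
        dy = abs(y[i] - y[j])
        if dy > half:
            dy = L - dy
        d2 = dx * dx + dy * dy
        if d2 < edges2[0] or d2 >= edges2[nbins]:
            continue
        lo = 0
        hi = nbins
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if d2 >= edges2[mid]:
                lo = mid
            else:
                hi = mid
        if tot[lo] >= max_pairs:
            continue
        tot[lo] += 1
        if species[i] == species[j]:
            same[lo] += 1
        full = True
        for k in range(nbins):
            if tot[k] < max_pairs:
                full = False
                break
        if full:
            break
    return same, tot
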