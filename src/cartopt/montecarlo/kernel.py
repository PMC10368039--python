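"""Numba photon-transport kernel for the cuvette sample-holder construct.

Geometry (z increases downward from the illuminated top surface, units mm)::

    z < 0                 ambient (index n_amb)
    0 .. wt               top glass window (clear, index n_win)
    wt .. wt + d          sample cylinder (radius rs) with lateral gap medium
                          out to the holder wall (radius rh); the sample's
                          bottom face is the plane z = wt + d - c + s*x
                          (c = cut depth, s = tilt slope; c = s = 0 is flat)
    wt + d .. wt + d + wb bottom glass window
    z > wt + d + wb       ambient

The holder wall at r = rh is perfectly absorbing (side loss).  Photon weight
is propagated with implicit-capture absorption, Henyey-Greenstein scattering,
and probabilistic Fresnel events at every dielectric interface.  Russian
roulette terminates low-weight photons; the realized roulette imbalance is
tallied explicitly so that every run conserves weight to float precision.

The random stream is an explicit xorshift64* generator (documented 64-bit
xorshift with a multiplicative output scramble), seeded through splitmix64,
so every tally is bit-reproducible for a given (inputs, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

# region codes
_WIN_TOP = 1
_SAMPLE = 2
_GAP = 3
_WIN_BOT = 4

# tally slots
T_RSPEC = 0
T_RDIFF = 1
T_TTOT = 2
T_ASAMP = 3
T_AGAP = 4
T_SIDE = 5
T_ROULETTE = 6
T_SUMR2 = 7
T_SUMT2 = 8
T_NSCAT = 9
N_TALLY = 10

_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True)
def _splitmix64(seed):
    z = uint64(seed) + uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    z = z ^ (z >> uint64(31))
    if z == uint64(0):
        z = uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True, inline="always")
def _u01(state):
    """xorshift64* uniform in [0, 1) with 53-bit resolution."""
    s = state[0]
    s ^= s >> uint64(12)
    s ^= s << uint64(25)
    s ^= s >> uint64(27)
    state[0] = s
    return float((s * uint64(0x2545F4914F6CDD1D)) >> uint64(11)) * _INV53


@njit(cache=True, inline="always")
def _fresnel(n1, n2, cos_i):
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _hg_cosine(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _scatter(ux, uy, uz, cos_t, phi):
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t if uz >= 0.0 else -cos_t
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nz = -sin_t * cos_p * den + uz * cos_t
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _cyl_exit(x, y, dx, dy, radius):
    """Distance to cylinder r=radius from inside; inf if never reached."""
    a = dx * dx + dy * dy
    if a <= 1e-300:
        return np.inf
    b = x * dx + y * dy
    c = x * x + y * y - radius * radius
    disc = b * b - a * c
    if disc <= 0.0:
        return np.inf
    t = (-b + np.sqrt(disc)) / a
    return t if t > 0.0 else np.inf


@njit(cache=True, inline="always")
def _cyl_enter(x, y, dx, dy, radius):
    """Nearest positive crossing of cylinder r=radius from outside."""
    a = dx * dx + dy * dy
    if a <= 1e-300:
        return np.inf
    b = x * dx + y * dy
    c = x * x + y * y - radius * radius
    disc = b * b - a * c
    if disc <= 0.0:
        return np.inf
    sq = np.sqrt(disc)
    t1 = (-b - sq) / a
    if t1 > 0.0:
        return t1
    t2 = (-b + sq) / a
    return t2 if t2 > 0.0 else np.inf


@njit(cache=True, inline="always")
def _plane_dist(z, dz, z0):
    if dz > 0.0 and z < z0:
        return (z0 - z) / dz
    if dz < 0.0 and z > z0:
        return (z0 - z) / dz
    return np.inf


@njit(cache=True, inline="always")
def _cut_plane_dist(x, z, dx, dz, zb0, slope):
    """Distance to the oblique bottom plane z = zb0 + slope*x."""
    v = z - zb0 - slope * x
    dv = dz - slope * dx
    if abs(dv) <= 1e-300:
        return np.inf
    t = -v / dv
    return t if t > 0.0 else np.inf


@njit(cache=True)
def _lambert_dir(state, nx, ny, nz):
    """Cosine-weighted direction in the hemisphere around unit normal n."""
    u1 = _u01(state)
    u2 = _u01(state)
    sin_t = np.sqrt(u1)
    cos_t = np.sqrt(1.0 - u1)
    phi = 2.0 * np.pi * u2
    # orthonormal tangent basis (t1, t2) for n
    if abs(nz) < 0.9:
        t1x, t1y, t1z = -ny, nx, 0.0
    else:
        t1x, t1y, t1z = 0.0, -nz, ny
    tn = np.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
    t1x /= tn
    t1y /= tn
    t1z /= tn
    t2x = ny * t1z - nz * t1y
    t2y = nz * t1x - nx * t1z
    t2z = nx * t1y - ny * t1x
    dx = sin_t * (np.cos(phi) * t1x + np.sin(phi) * t2x) + cos_t * nx
    dy = sin_t * (np.cos(phi) * t1y + np.sin(phi) * t2y) + cos_t * ny
    dz = sin_t * (np.cos(phi) * t1z + np.sin(phi) * t2z) + cos_t * nz
    return dx, dy, dz


@njit(cache=True)
def _refract(ux, uy, uz, nx, ny, nz, cos_i, eta):
    """Refract direction u across interface with normal n (n oriented along u)."""
    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
    cos_t = np.sqrt(max(0.0, 1.0 - sin_t2))
    tx = eta * (ux - cos_i * nx) + cos_t * nx
    ty = eta * (uy - cos_i * ny) + cos_t * ny
    tz = eta * (uz - cos_i * nz) + cos_t * nz
    norm = np.sqrt(tx * tx + ty * ty + tz * tz)
    return tx / norm, ty / norm, tz / norm


_EPS = 1e-9
_MAX_EVENTS = 4_000_000


@njit(cache=True)
def transport(
    n_photons,
    seed,
    mu_a,
    mu_s,
    g,
    n_samp,
    mu_a_gap,
    n_gap,
    n_win,
    n_amb,
    wt,
    wb,
    d,
    rs,
    rh,
    rb,
    cut_depth,
    cut_slope,
    rough,
    w_min,
    p_survive,
):
    """Transport ``n_photons`` photon packets; return the tally array.

    Tallies (all per launched photon, i.e. divided by n_photons at the end):
    specular R, diffuse R, total T, sample absorption, gap absorption, side
    loss, roulette imbalance, sum of squared per-photon R and T
    contributions, and the mean number of scattering events.
    """
    tal = np.zeros(N_TALLY, dtype=np.float64)
    state = np.empty(1, dtype=np.uint64)
    state[0] = _splitmix64(seed)

    zb0 = wt + d - cut_depth  # oblique-plane intercept at x = 0
    z_bot_win = wt + d
    z_exit = wt + d + wb
    has_cut = cut_depth > 0.0
    plane_norm = np.sqrt(1.0 + cut_slope * cut_slope)
    # plane normal pointing downward (out of the sample)
    pnx = -cut_slope / plane_norm
    pnz = 1.0 / plane_norm

    for _ in range(n_photons):
        # launch: uniform over the beam disk, normal incidence
        rr = rb * np.sqrt(_u01(state))
        phi0 = 2.0 * np.pi * _u01(state)
        x = rr * np.cos(phi0)
        y = rr * np.sin(phi0)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        nscat = 0
        wR = 0.0
        wT = 0.0

        # entry Fresnel at the air/top-window interface
        if _u01(state) < _fresnel(n_amb, n_win, 1.0):
            tal[T_RSPEC] += w
            continue
        region = _WIN_TOP
        z = _EPS

        alive = True
        events = 0
        while alive:
            events += 1
            if events > _MAX_EVENTS:
                tal[T_ROULETTE] += w  # bookkept as terminated weight
                break

            # medium of the current region
            if region == _SAMPLE:
                m_a = mu_a
                m_s = mu_s
                n_here = n_samp
            elif region == _GAP:
                m_a = mu_a_gap
                m_s = 0.0
                n_here = n_gap
            else:
                m_a = 0.0
                m_s = 0.0
                n_here = n_win
            m_t = m_a + m_s

            step = np.inf
            if m_t > 0.0:
                step = -np.log(1.0 - _u01(state)) / m_t

            # nearest boundary of the current region
            db = np.inf
            surf = -1  # 0 z=0 | 1 z=wt | 2 cut plane | 3 z=wt+d | 4 z=exit
            #            5 r=rs | 6 r=rh
            if region == _WIN_TOP:
                t0 = _plane_dist(z, uz, 0.0)
                if t0 < db:
                    db = t0
                    surf = 0
                t1 = _plane_dist(z, uz, wt)
                if t1 < db:
                    db = t1
                    surf = 1
                t6 = _cyl_exit(x, y, ux, uy, rh)
                if t6 < db:
                    db = t6
                    surf = 6
            elif region == _SAMPLE:
                t1 = _plane_dist(z, uz, wt)
                if t1 < db:
                    db = t1
                    surf = 1
                t2 = _cut_plane_dist(x, z, ux, uz, zb0, cut_slope)
                if t2 < db:
                    db = t2
                    surf = 2
                t5 = _cyl_exit(x, y, ux, uy, rs)
                if t5 < db:
                    db = t5
                    surf = 5
            elif region == _GAP:
                t1 = _plane_dist(z, uz, wt)
                if t1 < db:
                    db = t1
                    surf = 1
                t3 = _plane_dist(z, uz, z_bot_win)
                if t3 < db:
                    db = t3
                    surf = 3
                t6 = _cyl_exit(x, y, ux, uy, rh)
                if t6 < db:
                    db = t6
                    surf = 6
                r2 = x * x + y * y
                if r2 < rs * rs:
                    # under the cut face: the oblique plane is a boundary
                    t2 = _cut_plane_dist(x, z, ux, uz, zb0, cut_slope)
                    if t2 < db:
                        db = t2
                        surf = 2
                else:
                    t5 = _cyl_enter(x, y, ux, uy, rs)
                    if t5 < db:
                        db = t5
                        surf = 5
            else:  # _WIN_BOT
                t3 = _plane_dist(z, uz, z_bot_win)
                if t3 < db:
                    db = t3
                    surf = 3
                t4 = _plane_dist(z, uz, z_exit)
                if t4 < db:
                    db = t4
                    surf = 4
                t6 = _cyl_exit(x, y, ux, uy, rh)
                if t6 < db:
                    db = t6
                    surf = 6

            if step < db:
                # interaction inside the medium
                x += step * ux
                y += step * uy
                z += step * uz
                if m_t <= 0.0:
                    # unreachable: step finite implies m_t > 0
                    break
                albedo = m_s / m_t
                w_new = w * albedo
                if region == _SAMPLE:
                    tal[T_ASAMP] += w - w_new
                else:
                    tal[T_AGAP] += w - w_new
                w = w_new
                if w <= 0.0:
                    break
                if m_s > 0.0:
                    cos_t = _hg_cosine(g, _u01(state))
                    phi = 2.0 * np.pi * _u01(state)
                    ux, uy, uz = _scatter(ux, uy, uz, cos_t, phi)
                    nscat += 1
                # Russian roulette
                if w < w_min:
                    if _u01(state) < p_survive:
                        w_new = w / p_survive
                        tal[T_ROULETTE] += w - w_new  # negative: boost
                        w = w_new
                    else:
                        tal[T_ROULETTE] += w
                        break
                continue

            # boundary event
            x += db * ux
            y += db * uy
            z += db * uz

            if surf == 6:
                tal[T_SIDE] += w
                break

            if surf == 0:
                # window -> ambient (top exit)
                if _u01(state) < _fresnel(n_win, n_amb, abs(uz)):
                    uz = -uz
                    z = _EPS
                    continue
                if nscat > 0:
                    tal[T_RDIFF] += w
                    wR = w
                else:
                    tal[T_RSPEC] += w
                break

            if surf == 4:
                # window -> ambient (bottom exit)
                if _u01(state) < _fresnel(n_win, n_amb, abs(uz)):
                    uz = -uz
                    z = z_exit - _EPS
                    continue
                tal[T_TTOT] += w
                wT = w
                break

            if surf == 1:
                # plane z = wt between top window and sample/gap
                inside_rs = (x * x + y * y) < rs * rs
                if uz > 0.0:  # going down, leaving the top window
                    n_to = n_samp if inside_rs else n_gap
                    if _u01(state) < _fresnel(n_win, n_to, uz):
                        uz = -uz
                    else:
                        ux, uy, uz = _refract(ux, uy, uz, 0.0, 0.0, 1.0, uz, n_win / n_to)
                        region = _SAMPLE if inside_rs else _GAP
                else:  # going up into the top window
                    n_from = n_samp if region == _SAMPLE else n_gap
                    if _u01(state) < _fresnel(n_from, n_win, -uz):
                        uz = -uz
                    else:
                        ux, uy, uz = _refract(ux, uy, uz, 0.0, 0.0, -1.0, -uz, n_from / n_win)
                        region = _WIN_TOP
                x += _EPS * ux
                y += _EPS * uy
                z += _EPS * uz
                continue

            if surf == 3:
                # plane z = wt + d between bottom window and sample/gap
                inside_rs = (x * x + y * y) < rs * rs
                upper = _SAMPLE if (inside_rs and not has_cut) else _GAP
                if uz > 0.0:  # entering the bottom window
                    n_from = n_samp if region == _SAMPLE else n_gap
                    rough_here = rough == 1 and region == _SAMPLE and not has_cut
                    if rough_here:
                        # fully rough (matte) interface: Fresnel split at
                        # the actual incidence, both outgoing streams
                        # redistributed Lambertian
                        if _u01(state) < _fresnel(n_from, n_win, uz):
                            ux, uy, uz = _lambert_dir(state, 0.0, 0.0, -1.0)
                        else:
                            ux, uy, uz = _lambert_dir(state, 0.0, 0.0, 1.0)
                            region = _WIN_BOT
                        nscat += 1
                    else:
                        if _u01(state) < _fresnel(n_from, n_win, uz):
                            uz = -uz
                        else:
                            ux, uy, uz = _refract(ux, uy, uz, 0.0, 0.0, 1.0, uz, n_from / n_win)
                            region = _WIN_BOT
                else:  # leaving the bottom window upward
                    n_to = n_samp if upper == _SAMPLE else n_gap
                    rough_here = rough == 1 and upper == _SAMPLE and not has_cut
                    if rough_here:
                        if _u01(state) < _fresnel(n_win, n_to, -uz):
                            ux, uy, uz = _lambert_dir(state, 0.0, 0.0, 1.0)
                        else:
                            ux, uy, uz = _lambert_dir(state, 0.0, 0.0, -1.0)
                            region = upper
                        nscat += 1
                    else:
                        if _u01(state) < _fresnel(n_win, n_to, -uz):
                            uz = -uz
                        else:
                            ux, uy, uz = _refract(ux, uy, uz, 0.0, 0.0, -1.0, -uz, n_win / n_to)
                            region = upper
                x += _EPS * ux
                y += _EPS * uy
                z += _EPS * uz
                continue

            if surf == 2:
                # oblique bottom face of the sample (cut plane)
                if (x * x + y * y) >= rs * rs:
                    # outside the sample footprint: not a real interface
                    x += _EPS * ux
                    y += _EPS * uy
                    z += _EPS * uz
                    continue
                below = _GAP if has_cut else _WIN_BOT
                n_below = n_gap if has_cut else n_win
                # normal (pnx, 0, pnz) points downward out of the sample
                dot = ux * pnx + uz * pnz
                if region == _SAMPLE and dot > 0.0:
                    if rough == 1:
                        if _u01(state) < _fresnel(n_samp, n_below, dot):
                            ux, uy, uz = _lambert_dir(state, -pnx, 0.0, -pnz)
                        else:
                            ux, uy, uz = _lambert_dir(state, pnx, 0.0, pnz)
                            region = below
                        nscat += 1
                    else:
                        if _u01(state) < _fresnel(n_samp, n_below, dot):
                            ux -= 2.0 * dot * pnx
                            uz -= 2.0 * dot * pnz
                        else:
                            ux, uy, uz = _refract(ux, uy, uz, pnx, 0.0, pnz, dot, n_samp / n_below)
                            region = below
                elif region != _SAMPLE and dot < 0.0:
                    # crossing upward into the sample through the cut face
                    n_from = n_gap if region == _GAP else n_win
                    if rough == 1:
                        if _u01(state) < _fresnel(n_from, n_samp, -dot):
                            ux, uy, uz = _lambert_dir(state, pnx, 0.0, pnz)
                        else:
                            ux, uy, uz = _lambert_dir(state, -pnx, 0.0, -pnz)
                            region = _SAMPLE
                        nscat += 1
                    else:
                        if _u01(state) < _fresnel(n_from, n_samp, -dot):
                            ux -= 2.0 * dot * pnx
                            uz -= 2.0 * dot * pnz
                        else:
                            ux, uy, uz = _refract(ux, uy, uz, -pnx, 0.0, -pnz, -dot, n_from / n_samp)
                            region = _SAMPLE
                x += _EPS * ux
                y += _EPS * uy
                z += _EPS * uz
                continue

            if surf == 5:
                # lateral cylinder r = rs between sample and gap
                rnorm = np.sqrt(x * x + y * y)
                if rnorm <= 0.0:
                    break
                cnx = x / rnorm
                cny = y / rnorm
                dot = ux * cnx + uy * cny
                if region == _SAMPLE:
                    # only a true interface if the far side is gap at this z
                    if _u01(state) < _fresnel(n_samp, n_gap, abs(dot)):
                        ux -= 2.0 * dot * cnx
                        uy -= 2.0 * dot * cny
                    else:
                        ux, uy, uz = _refract(ux, uy, uz, cnx, cny, 0.0, dot, n_samp / n_gap)
                        region = _GAP
                else:
                    # gap photon crossing inward: sample only if above the
                    # cut plane at the crossing point
                    if z < zb0 + cut_slope * x:
                        if _u01(state) < _fresnel(n_gap, n_samp, abs(dot)):
                            ux -= 2.0 * dot * cnx
                            uy -= 2.0 * dot * cny
                        else:
                            ux, uy, uz = _refract(ux, uy, uz, -cnx, -cny, 0.0, -dot, n_gap / n_samp)
                            region = _SAMPLE
                    # else: same medium on both sides, pass through
                x += _EPS * ux
                y += _EPS * uy
                z += _EPS * uz
                continue

            # no boundary reachable (should not happen): drop the weight
            tal[T_ROULETTE] += w
            break

        tal[T_SUMR2] += wR * wR
        tal[T_SUMT2] += wT * wT
        tal[T_NSCAT] += nscat

    return tal
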