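"""Low-level numba kernels for the off-lattice cell simulator.

All geometry lives on a dense uniform grid of cubic buckets whose edge equals
the cell diameter, so any two touching cells are at most one bucket apart and
bucket occupancy is bounded by packing.  Kernels operate on preallocated
arrays owned by the Python-side simulation loop; they never allocate per
event.  Status codes: 0 ok, 1 bucket overflow, 2 push-cascade budget
exceeded, 3 cell left the simulation box.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BUCKET_OVERFLOW = 1
STATUS_CASCADE_BUDGET = 2
STATUS_OUT_OF_BOUNDS = 3


@njit(cache=True)
def seed_kernel_rng(seed):
    # numba keeps its own np.random state; seed it once per run
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _flat_bin(pos, i, origin, inv_bw, nb, dim):
    flat = 0
    for d in range(dim):
        c = int((pos[i, d] - origin) * inv_bw)
        if c < 0 or c >= nb:
            return -1
        flat = flat * nb + c
    return flat


@njit(cache=True, inline="always")
def _flat_bin_point(x, y, z, origin, inv_bw, nb, dim):
    cx = int((x - origin) * inv_bw)
    if cx < 0 or cx >= nb:
        return -1
    cy = int((y - origin) * inv_bw)
    if cy < 0 or cy >= nb:
        return -1
    flat = cx * nb + cy
    if dim == 3:
        cz = int((z - origin) * inv_bw)
        if cz < 0 or cz >= nb:
            return -1
        flat = flat * nb + cz
    return flat


@njit(cache=True)
def grid_insert(gcount, gcells, flat, slot):
    n = gcount[flat]
    if n >= gcells.shape[1]:
        return False
    gcells[flat, n] = slot
    gcount[flat] = n + 1
    return True


@njit(cache=True)
def grid_remove(gcount, gcells, flat, slot):
    n = gcount[flat]
    for k in range(n):
        if gcells[flat, k] == slot:
            gcells[flat, k] = gcells[flat, n - 1]
            gcount[flat] = n - 1
            return True
    return False


@njit(cache=True)
def bin_of(pos, i, origin, inv_bw, nb, dim):
    return _flat_bin(pos, i, origin, inv_bw, nb, dim)


@njit(cache=True, inline="always")
def _dist2(pos, i, j, dim):
    s = 0.0
    for d in range(dim):
        dx = pos[i, d] - pos[j, d]
        s += dx * dx
    return s


@njit(cache=True)
def count_within(pos, gcount, gcells, origin, inv_bw, nb, dim, slot, radius):
    """Number of OTHER cells with centre within `radius` of cell `slot`."""
    r2 = radius * radius
    reach = int(radius * inv_bw) + 1
    cnt = 0
    cx = int((pos[slot, 0] - origin) * inv_bw)
    cy = int((pos[slot, 1] - origin) * inv_bw)
    if dim == 2:
        for ix in range(max(0, cx - reach), min(nb, cx + reach + 1)):
            for iy in range(max(0, cy - reach), min(nb, cy + reach + 1)):
                flat = ix * nb + iy
                for k in range(gcount[flat]):
                    o = gcells[flat, k]
                    if o != slot and _dist2(pos, slot, o, dim) <= r2:
                        cnt += 1
    else:
        cz = int((pos[slot, 2] - origin) * inv_bw)
        for ix in range(max(0, cx - reach), min(nb, cx + reach + 1)):
            for iy in range(max(0, cy - reach), min(nb, cy + reach + 1)):
                for iz in range(max(0, cz - reach), min(nb, cz + reach + 1)):
                    flat = (ix * nb + iy) * nb + iz
                    for k in range(gcount[flat]):
                        o = gcells[flat, k]
                        if o != slot and _dist2(pos, slot, o, dim) <= r2:
                            cnt += 1
    return cnt


@njit(cache=True)
def _gather_overlaps(pos, gcount, gcells, origin, inv_bw, nb, dim, c,
                     min_dist, buf):
    """Collect slots overlapping cell c (dist < min_dist) into buf; return count."""
    r2 = (min_dist - 1e-12) ** 2
    reach = int(min_dist * inv_bw) + 1
    n = 0
    cx = int((pos[c, 0] - origin) * inv_bw)
    cy = int((pos[c, 1] - origin) * inv_bw)
    if dim == 2:
        for ix in range(max(0, cx - reach), min(nb, cx + reach + 1)):
            for iy in range(max(0, cy - reach), min(nb, cy + reach + 1)):
                flat = ix * nb + iy
                for k in range(gcount[flat]):
                    o = gcells[flat, k]
                    if o != c and _dist2(pos, c, o, dim) < r2:
                        if n < buf.shape[0]:
                            buf[n] = o
                        n += 1
    else:
        cz = int((pos[c, 2] - origin) * inv_bw)
        for ix in range(max(0, cx - reach), min(nb, cx + reach + 1)):
            for iy in range(max(0, cy - reach), min(nb, cy + reach + 1)):
                for iz in range(max(0, cz - reach), min(nb, cz + reach + 1)):
                    flat = (ix * nb + iy) * nb + iz
                    for k in range(gcount[flat]):
                        o = gcells[flat, k]
                        if o != c and _dist2(pos, c, o, dim) < r2:
                            if n < buf.shape[0]:
                                buf[n] = o
                            n += 1
    return n


@njit(cache=True)
def resolve_overlaps(pos, gcount, gcells, origin, inv_bw, nb, dim, seed_slot,
                     min_dist, margin, queue, nbr_buf, moved_pos, max_pushes):
    """Width-first push cascade starting from `seed_slot`.

    Each overlapped neighbour is pushed along the connecting axis to distance
    min_dist + margin, its new position recorded in moved_pos, and enqueued
    (FIFO).  Neighbourhood order is shuffled before pushing.  Returns
    (n_moved, status).
    """
    head = 0
    tail = 0
    qcap = queue.shape[0]
    queue[tail] = seed_slot
    tail += 1
    n_moved = 0
    pushes = 0
    target = min_dist + margin
    while head != tail:
        c = queue[head]
        head += 1
        if head == qcap:
            head = 0
        n_ov = _gather_overlaps(pos, gcount, gcells, origin, inv_bw, nb, dim,
                                c, min_dist, nbr_buf)
        if n_ov > nbr_buf.shape[0]:
            return n_moved, STATUS_BUCKET_OVERFLOW
        # shuffle neighbourhood order (Fisher-Yates)
        for k in range(n_ov - 1, 0, -1):
            j = np.random.randint(0, k + 1)
            tmp = nbr_buf[k]
            nbr_buf[k] = nbr_buf[j]
            nbr_buf[j] = tmp
        for k in range(n_ov):
            o = nbr_buf[k]
            d2 = _dist2(pos, c, o, dim)
            if d2 >= (min_dist - 1e-12) ** 2:
                continue  # already resolved by an earlier push this round
            old_flat = _flat_bin(pos, o, origin, inv_bw, nb, dim)
            dist = np.sqrt(d2)
            if dist < 1e-9:
                # coincident centres: push in a random direction
                s = 0.0
                uvec = np.empty(dim)
                for d in range(dim):
                    uvec[d] = np.random.normal()
                    s += uvec[d] * uvec[d]
                s = np.sqrt(s)
                for d in range(dim):
                    pos[o, d] = pos[c, d] + uvec[d] / s * target
            else:
                for d in range(dim):
                    u = (pos[o, d] - pos[c, d]) / dist
                    pos[o, d] = pos[c, d] + u * target
            new_flat = _flat_bin(pos, o, origin, inv_bw, nb, dim)
            if new_flat < 0:
                return n_moved, STATUS_OUT_OF_BOUNDS
            if new_flat != old_flat:
                grid_remove(gcount, gcells, old_flat, o)
                if not grid_insert(gcount, gcells, new_flat, o):
                    return n_moved, STATUS_BUCKET_OVERFLOW
            if n_moved < moved_pos.shape[0]:
                for d in range(dim):
                    moved_pos[n_moved, d] = pos[o, d]
                n_moved += 1
            else:
                return n_moved, STATUS_CASCADE_BUDGET
            pushes += 1
            if pushes > max_pushes:
                return n_moved, STATUS_CASCADE_BUDGET
            queue[tail] = o
            tail += 1
            if tail == qcap:
                tail = 0
            if tail == head:
                return n_moved, STATUS_CASCADE_BUDGET
    return n_moved, STATUS_OK


@njit(cache=True)
def place_and_resolve(pos, gcount, gcells, origin, inv_bw, nb, dim,
                      mother, daughter, dirvec, min_dist, margin,
                      queue, nbr_buf, moved_pos, max_pushes):
    """Place `daughter` at distance min_dist from `mother` along `dirvec`
    (unit vector) and resolve the resulting overlaps."""
    for d in range(dim):
        pos[daughter, d] = pos[mother, d] + dirvec[d] * min_dist
    flat = _flat_bin(pos, daughter, origin, inv_bw, nb, dim)
    if flat < 0:
        return 0, STATUS_OUT_OF_BOUNDS
    if not grid_insert(gcount, gcells, flat, daughter):
        return 0, STATUS_BUCKET_OVERFLOW
    return resolve_overlaps(pos, gcount, gcells, origin, inv_bw, nb, dim,
                            daughter, min_dist, margin, queue, nbr_buf,
                            moved_pos, max_pushes)


@njit(cache=True)
def update_densities(pos, gcount, gcells, origin, inv_bw, nb, dim,
                     changed_pos, n_changed, stamp, stamp_val, affected,
                     density_radius, slack, b0, rho_c, ball_measure,
                     brate_alive, pos_in_alive):
    """Recompute birth rates for every cell whose density window contains a
    changed position.  Returns (delta_total_birth_rate, n_affected)."""
    search = density_radius + slack
    n_aff = 0
    # gather affected cells, deduplicated with the stamp array
    for ci in range(n_changed):
        px = changed_pos[ci, 0]
        py = changed_pos[ci, 1]
        pz = changed_pos[ci, 2] if dim == 3 else 0.0
        flat0 = _flat_bin_point(px, py, pz, origin, inv_bw, nb, dim)
        if flat0 < 0:
            continue
        reach = int(search * inv_bw) + 1
        cx = int((px - origin) * inv_bw)
        cy = int((py - origin) * inv_bw)
        s2 = search * search
        if dim == 2:
            for ix in range(max(0, cx - reach), min(nb, cx + reach + 1)):
                for iy in range(max(0, cy - reach), min(nb, cy + reach + 1)):
                    flat = ix * nb + iy
                    for k in range(gcount[flat]):
                        o = gcells[flat, k]
                        dx = pos[o, 0] - px
                        dy = pos[o, 1] - py
                        if dx * dx + dy * dy <= s2 and stamp[o] != stamp_val:
                            stamp[o] = stamp_val
                            if n_aff < affected.shape[0]:
                                affected[n_aff] = o
                                n_aff += 1
        else:
            cz = int((pz - origin) * inv_bw)
            for ix in range(max(0, cx - reach), min(nb, cx + reach + 1)):
                for iy in range(max(0, cy - reach), min(nb, cy + reach + 1)):
                    for iz in range(max(0, cz - reach), min(nb, cz + reach + 1)):
                        flat = (ix * nb + iy) * nb + iz
                        for k in range(gcount[flat]):
                            o = gcells[flat, k]
                            dx = pos[o, 0] - px
                            dy = pos[o, 1] - py
                            dz = pos[o, 2] - pz
                            if dx * dx + dy * dy + dz * dz <= s2 and stamp[o] != stamp_val:
                                stamp[o] = stamp_val
                                if n_aff < affected.shape[0]:
                                    affected[n_aff] = o
                                    n_aff += 1
    delta = 0.0
    for k in range(n_aff):
        o = affected[k]
        cnt = count_within(pos, gcount, gcells, origin, inv_bw, nb, dim, o,
                           density_radius)
        rho = cnt / ball_measure
        newb = b0 * (1.0 - rho / rho_c)
        if newb < 0.0:
            newb = 0.0
        ai = pos_in_alive[o]
        delta += newb - brate_alive[ai]
        brate_alive[ai] = newb
    return delta, n_aff


@njit(cache=True)
def min_pairwise_dist(pos, slots, n):
    """Brute-force minimum pairwise centre distance among the given slots."""
    best = np.inf
    dim = pos.shape[1]
    for a in range(n):
        i = slots[a]
        for bjd in range(a + 1, n):
            j = slots[bjd]
            s = 0.0
            for d in range(dim):
                dx = pos[i, d] - pos[j, d]
                s += dx * dx
            if s < best:
                best = s
    return np.sqrt(best)
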