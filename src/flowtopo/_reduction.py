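"""Numba kernels for Vietoris-Rips persistence.

Pairs in dimension d are computed by reducing the anti-transposed boundary
matrix (columns = d-simplices in decreasing filtration order, rows =
(d+1)-cofacets), with two standard accelerations:

* clearing -- columns of simplices already paired as deaths in dimension
  d-1 are skipped (they provably reduce to zero);
* apparent pairs -- a column whose minimal cofacet has the column as its
  maximal facet is paired immediately; its raw coboundary is materialised
  on demand if a later reduction needs it.

Simplices are packed into int64 keys (vertices in increasing order,
base-n digits); ties in filtration value break by packed key, i.e.
lexicographic vertex order.  The filtration is truncated at the enclosing
radius, which is exact for homology in dimensions >= 1.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import Dict
from numba.types import int64


@njit(cache=True)
def mst_prim(n, dm):
    """Minimum spanning tree of the complete graph on dm.

    Returns (weights, edge_keys) with edge_keys packed as i*n+j, i<j.
    """
    in_tree = np.zeros(n, np.bool_)
    dist = np.full(n, np.inf)
    src = np.full(n, -1, np.int64)
    dist[0] = 0.0
    m = n - 1 if n > 1 else 0
    keys = np.empty(max(m, 1), np.int64)
    w = np.empty(max(m, 1), np.float64)
    for it in range(n):
        best = -1
        bd = np.inf
        for v in range(n):
            if not in_tree[v] and dist[v] < bd:
                bd = dist[v]
                best = v
        in_tree[best] = True
        if src[best] >= 0:
            a, b = (src[best], best) if src[best] < best else (best, src[best])
            keys[it - 1] = a * n + b
            w[it - 1] = bd
        for v in range(n):
            if not in_tree[v] and dm[best, v] < dist[v]:
                dist[v] = dm[best, v]
                src[v] = best
    return w[:m], keys[:m]


@njit(cache=True, inline="always")
def _edge_cofacets(e, n, dm, thresh, outid, outv):
    """Cofacet triangles of edge e, sorted ascending by (value, key)."""
    i = e // n
    j = e % n
    fe = dm[i, j]
    n2 = n * n
    wlen = 0
    for t in range(n):
        if t == i or t == j:
            continue
        dit = dm[i, t]
        djt = dm[j, t]
        if dit <= thresh and djt <= thresh:
            v = fe
            if dit > v:
                v = dit
            if djt > v:
                v = djt
            if t < i:
                tri = t * n2 + i * n + j
            elif t > j:
                tri = i * n2 + j * n + t
            else:
                tri = i * n2 + t * n + j
            p = wlen
            while p > 0 and (outv[p - 1] > v or (outv[p - 1] == v and outid[p - 1] > tri)):
                outv[p] = outv[p - 1]
                outid[p] = outid[p - 1]
                p -= 1
            outv[p] = v
            outid[p] = tri
            wlen += 1
    return wlen


@njit(cache=True, inline="always")
def _tri_cofacets(tri, n, dm, thresh, outid, outv):
    """Cofacet tetrahedra of a triangle, sorted ascending by (value, key)."""
    n2 = n * n
    n3 = n2 * n
    i = tri // n2
    rem = tri % n2
    j = rem // n
    k = rem % n
    ft = dm[i, j]
    if dm[i, k] > ft:
        ft = dm[i, k]
    if dm[j, k] > ft:
        ft = dm[j, k]
    wlen = 0
    for t in range(n):
        if t == i or t == j or t == k:
            continue
        dit = dm[i, t]
        djt = dm[j, t]
        dkt = dm[k, t]
        if dit <= thresh and djt <= thresh and dkt <= thresh:
            v = ft
            if dit > v:
                v = dit
            if djt > v:
                v = djt
            if dkt > v:
                v = dkt
            if t < i:
                tet = t * n3 + i * n2 + j * n + k
            elif t < j:
                tet = i * n3 + t * n2 + j * n + k
            elif t < k:
                tet = i * n3 + j * n2 + t * n + k
            else:
                tet = i * n3 + j * n2 + k * n + t
            p = wlen
            while p > 0 and (outv[p - 1] > v or (outv[p - 1] == v and outid[p - 1] > tet)):
                outv[p] = outv[p - 1]
                outid[p] = outid[p - 1]
                p -= 1
            outv[p] = v
            outid[p] = tet
            wlen += 1
    return wlen


@njit(cache=True, inline="always")
def _max_facet_of_triangle(tri, n, dm):
    """Packed key of the maximal facet edge by (value, key)."""
    n2 = n * n
    x = tri // n2
    rem = tri % n2
    y = rem // n
    z = rem % n
    bestk = x * n + y
    bestv = dm[x, y]
    if dm[x, z] > bestv or (dm[x, z] == bestv and x * n + z > bestk):
        bestv = dm[x, z]
        bestk = x * n + z
    if dm[y, z] > bestv or (dm[y, z] == bestv and y * n + z > bestk):
        bestv = dm[y, z]
        bestk = y * n + z
    return bestk


@njit(cache=True, inline="always")
def _max_facet_of_tetra(tet, n, dm):
    """Packed key of the maximal facet triangle by (value, key)."""
    n2 = n * n
    n3 = n2 * n
    a = tet // n3
    rem = tet % n3
    b = rem // n2
    rem = rem % n2
    c = rem // n
    d = rem % n
    bestk = np.int64(-1)
    bestv = -1.0
    for drop in range(4):
        if drop == 0:
            x, y, z = b, c, d
        elif drop == 1:
            x, y, z = a, c, d
        elif drop == 2:
            x, y, z = a, b, d
        else:
            x, y, z = a, b, c
        v = dm[x, y]
        if dm[x, z] > v:
            v = dm[x, z]
        if dm[y, z] > v:
            v = dm[y, z]
        key = x * n2 + y * n + z
        if v > bestv or (v == bestv and key > bestk):
            bestv = v
            bestk = key
    return bestk


@njit(cache=True)
def pairs_dim1(n, dm, thresh, cleared_keys):
    """(edge, triangle) persistence pairs of the VR filtration.

    cleared_keys: packed edge keys already paired as dim-0 deaths (MST
    edges).  Returns (births, deaths, paired_triangle_keys); the last is
    every triangle claimed as a pivot, for clearing in dimension 2.
    """
    ne = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dm[i, j] <= thresh:
                ne += 1
    ev = np.empty(max(ne, 1), np.float64)
    ekey = np.empty(max(ne, 1), np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dm[i, j] <= thresh:
                ev[k] = dm[i, j]
                ekey[k] = i * n + j
                k += 1
    order = np.argsort(ev[:ne], kind="mergesort")
    ev = ev[:ne][order]
    ekey = ekey[:ne][order]
    cleared = Dict.empty(int64, int64)
    for q in range(cleared_keys.shape[0]):
        cleared[cleared_keys[q]] = 1

    births = np.empty(max(ne, 1), np.float64)
    deaths = np.empty(max(ne, 1), np.float64)
    npairs = 0
    # pivot_of[cofacet] = stored column id >= 0, or -(simplex_key + 2) for
    # an apparent pair whose raw coboundary is rebuilt on demand
    pivot_of = Dict.empty(int64, int64)
    poolid = np.empty(max(ne, 1) * 4, np.int64)
    poolv = np.empty(max(ne, 1) * 4, np.float64)
    col_start = np.empty(max(ne, 1), np.int64)
    col_len = np.empty(max(ne, 1), np.int64)
    pool_pos = 0
    ncols = 0
    curid = np.empty(4 * n + 4, np.int64)
    curv = np.empty(4 * n + 4, np.float64)
    tmpid = np.empty(4 * n + 4, np.int64)
    tmpv = np.empty(4 * n + 4, np.float64)
    cofid = np.empty(n, np.int64)
    cofv = np.empty(n, np.float64)

    paired = np.empty(max(ne, 1), np.int64)
    npaired = 0

    for c_ in range(ne - 1, -1, -1):
        e = ekey[c_]
        if e in cleared:
            continue
        fe = ev[c_]
        wlen = _edge_cofacets(e, n, dm, thresh, cofid, cofv)
        if wlen == 0:
            continue
        tau0 = cofid[0]
        if cofv[0] == fe and tau0 not in pivot_of:
            if _max_facet_of_triangle(tau0, n, dm) == e:
                pivot_of[tau0] = -(e + 2)
                paired[npaired] = tau0
                npaired += 1
                continue
        clen = wlen
        for q in range(wlen):
            curid[q] = cofid[q]
            curv[q] = cofv[q]
        while clen > 0:
            piv = curid[0]
            if piv not in pivot_of:
                break
            pc = pivot_of[piv]
            if pc >= 0:
                s = col_start[pc]
                l = int(col_len[pc])
                othid = poolid[s : s + l]
                othv = poolv[s : s + l]
            else:
                oe = -pc - 2
                l = _edge_cofacets(oe, n, dm, thresh, cofid, cofv)
                othid = cofid[:l]
                othv = cofv[:l]
            need = clen + l
            if need > tmpid.shape[0]:
                tmpid = np.empty(need * 2, np.int64)
                tmpv = np.empty(need * 2, np.float64)
            a = 0
            b = 0
            m = 0
            while a < clen and b < l:
                xa = curid[a]
                yb = othid[b]
                if xa == yb:
                    a += 1
                    b += 1
                else:
                    xv = curv[a]
                    yv = othv[b]
                    if xv < yv or (xv == yv and xa < yb):
                        tmpid[m] = xa
                        tmpv[m] = xv
                        m += 1
                        a += 1
                    else:
                        tmpid[m] = yb
                        tmpv[m] = yv
                        m += 1
                        b += 1
            while a < clen:
                tmpid[m] = curid[a]
                tmpv[m] = curv[a]
                m += 1
                a += 1
            while b < l:
                tmpid[m] = othid[b]
                tmpv[m] = othv[b]
                m += 1
                b += 1
            if m > curid.shape[0]:
                curid = np.empty(m * 2, np.int64)
                curv = np.empty(m * 2, np.float64)
            for q in range(m):
                curid[q] = tmpid[q]
                curv[q] = tmpv[q]
            clen = m
        if clen > 0:
            piv = curid[0]
            if pool_pos + clen > poolid.shape[0]:
                cap = max(poolid.shape[0] * 2, pool_pos + clen)
                a1 = np.empty(cap, np.int64)
                a1[:pool_pos] = poolid[:pool_pos]
                poolid = a1
                a2 = np.empty(cap, np.float64)
                a2[:pool_pos] = poolv[:pool_pos]
                poolv = a2
            col_start[ncols] = pool_pos
            col_len[ncols] = clen
            for q in range(clen):
                poolid[pool_pos + q] = curid[q]
                poolv[pool_pos + q] = curv[q]
            pool_pos += clen
            pivot_of[piv] = ncols
            ncols += 1
            paired[npaired] = piv
            npaired += 1
            fd = curv[0]
            if fd > fe:
                births[npairs] = fe
                deaths[npairs] = fd
                npairs += 1
    return births[:npairs].copy(), deaths[:npairs].copy(), paired[:npaired].copy()


@njit(cache=True)
def pairs_dim2(n, dm, thresh, cleared_keys):
    """(triangle, tetrahedron) persistence pairs of the VR filtration.

    cleared_keys: packed triangle keys paired as dim-1 deaths.
    """
    n2 = n * n
    nt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dm[i, j] > thresh:
                continue
            for k in range(j + 1, n):
                if dm[i, k] <= thresh and dm[j, k] <= thresh:
                    nt += 1
    tv = np.empty(max(nt, 1), np.float64)
    tkey = np.empty(max(nt, 1), np.int64)
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            dij = dm[i, j]
            if dij > thresh:
                continue
            for k in range(j + 1, n):
                dik = dm[i, k]
                djk = dm[j, k]
                if dik <= thresh and djk <= thresh:
                    v = dij
                    if dik > v:
                        v = dik
                    if djk > v:
                        v = djk
                    tv[c] = v
                    tkey[c] = i * n2 + j * n + k
                    c += 1
    order = np.argsort(tv[:nt], kind="mergesort")
    tv = tv[:nt][order]
    tkey = tkey[:nt][order]
    cleared = Dict.empty(int64, int64)
    for q in range(cleared_keys.shape[0]):
        cleared[cleared_keys[q]] = 1

    births = np.empty(max(nt, 1), np.float64)
    deaths = np.empty(max(nt, 1), np.float64)
    npairs = 0
    pivot_of = Dict.empty(int64, int64)
    poolid = np.empty(max(nt, 1) * 4, np.int64)
    poolv = np.empty(max(nt, 1) * 4, np.float64)
    col_start = np.empty(max(nt, 1), np.int64)
    col_len = np.empty(max(nt, 1), np.int64)
    pool_pos = 0
    ncols = 0
    curid = np.empty(4 * n + 4, np.int64)
    curv = np.empty(4 * n + 4, np.float64)
    tmpid = np.empty(4 * n + 4, np.int64)
    tmpv = np.empty(4 * n + 4, np.float64)
    cofid = np.empty(n, np.int64)
    cofv = np.empty(n, np.float64)

    for c_ in range(nt - 1, -1, -1):
        tri = tkey[c_]
        if tri in cleared:
            continue
        ft = tv[c_]
        wlen = _tri_cofacets(tri, n, dm, thresh, cofid, cofv)
        if wlen == 0:
            continue
        tau0 = cofid[0]
        if cofv[0] == ft and tau0 not in pivot_of:
            if _max_facet_of_tetra(tau0, n, dm) == tri:
                pivot_of[tau0] = -(tri + 2)
                continue
        clen = wlen
        for q in range(wlen):
            curid[q] = cofid[q]
            curv[q] = cofv[q]
        while clen > 0:
            piv = curid[0]
            if piv not in pivot_of:
                break
            pc = pivot_of[piv]
            if pc >= 0:
                s = col_start[pc]
                l = int(col_len[pc])
                othid = poolid[s : s + l]
                othv = poolv[s : s + l]
            else:
                otri = -pc - 2
                l = _tri_cofacets(otri, n, dm, thresh, cofid, cofv)
                othid = cofid[:l]
                othv = cofv[:l]
            need = clen + l
            if need > tmpid.shape[0]:
                tmpid = np.empty(need * 2, np.int64)
                tmpv = np.empty(need * 2, np.float64)
            a = 0
            b = 0
            m = 0
            while a < clen and b < l:
                xa = curid[a]
                yb = othid[b]
                if xa == yb:
                    a += 1
                    b += 1
                else:
                    xv = curv[a]
                    yv = othv[b]
                    if xv < yv or (xv == yv and xa < yb):
                        tmpid[m] = xa
                        tmpv[m] = xv
                        m += 1
                        a += 1
                    else:
                        tmpid[m] = yb
                        tmpv[m] = yv
                        m += 1
                        b += 1
            while a < clen:
                tmpid[m] = curid[a]
                tmpv[m] = curv[a]
                m += 1
                a += 1
            while b < l:
                tmpid[m] = othid[b]
                tmpv[m] = othv[b]
                m += 1
                b += 1
            if m > curid.shape[0]:
                curid = np.empty(m * 2, np.int64)
                curv = np.empty(m * 2, np.float64)
            for q in range(m):
                curid[q] = tmpid[q]
                curv[q] = tmpv[q]
            clen = m
        if clen > 0:
            piv = curid[0]
            if pool_pos + clen > poolid.shape[0]:
                cap = max(poolid.shape[0] * 2, pool_pos + clen)
                a1 = np.empty(cap, np.int64)
                a1[:pool_pos] = poolid[:pool_pos]
                poolid = a1
                a2 = np.empty(cap, np.float64)
                a2[:pool_pos] = poolv[:pool_pos]
                poolv = a2
            col_start[ncols] = pool_pos
            col_len[ncols] = clen
            for q in range(clen):
                poolid[pool_pos + q] = curid[q]
                poolv[pool_pos + q] = curv[q]
            pool_pos += clen
            pivot_of[piv] = ncols
            ncols += 1
            fd = curv[0]
            if fd > ft:
                births[npairs] = ft
                deaths[npairs] = fd
                npairs += 1
    return births[:npairs].copy(), deaths[:npairs].copy()
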