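import numpy as np
from vsimri.physics import PhysicsConfig
from vsimri.fieldshift import compute_field_shift

phys = PhysicsConfig()
n=64; c=n//2
occ = np.zeros((n,n,n), bool); occ[c,c,c]=True
f = compute_field_shift(occ, phys).delta_omega
amp = phys.gamma*phys.B0*phys.delta_chi_field/(4*np.pi)
for p in [(2,0,0),(4,0,0),(6,0,0),(10,0,0),(0,0,2),(0,0,4),(0,0,6),(0,0,10),(4,0,4),(3,3,3)]:
    dx,dy,dz=p; r2=dx*dx+dy*dy+dz*dz
    exp = amp*(3*dz*dz/r2-1)/r2**1.5
    print(p, "got", f[c+dx,c+dy,c+dz], "expected", exp)
print("center value:", f[c,c,c], "sum:", f.sum())
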