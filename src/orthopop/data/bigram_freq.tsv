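bigram	count_per_million
aa	0.0000
ab	2085.5057
ac	5908.9329
ad	4518.5958
ae	0.0000
af	2085.5057
ag	3475.8429
ah	0.0000
ai	8689.6072
aj	0.0000
ak	4171.0115
al	12513.0344
am	7646.8544
an	11470.2815
ao	0.0000
ap	4171.0115
aq	0.0000
ar	16336.4616
as	7994.4387
at	9384.7758
au	695.1686
av	3475.8429
aw	3128.2586
ax	347.5843
ay	3475.8429
az	1737.9214
ba	4866.1800
bb	0.0000
bc	0.0000
bd	0.0000
be	6256.5172
bf	0.0000
bg	0.0000
bh	0.0000
bi	2085.5057
bj	0.0000
bk	0.0000
bl	1390.3372
bm	0.0000
bn	0.0000
bo	5561.3486
bp	0.0000
bq	0.0000
br	1390.3372
bs	347.5843
bt	347.5843
bu	2780.6743
bv	0.0000
bw	0.0000
bx	0.0000
by	695.1686
bz	0.0000
ca	6604.1015
cb	0.0000
cc	0.0000
cd	0.0000
ce	4171.0115
cf	0.0000
cg	0.0000
ch	4518.5958
ci	1042.7529
cj	0.0000
ck	8342.0229
cl	2433.0900
cm	0.0000
cn	0.0000
co	7299.2701
cp	0.0000
cq	0.0000
cr	1390.3372
cs	0.0000
ct	1390.3372
cu	2433.0900
cv	0.0000
cw	0.0000
cx	0.0000
cy	0.0000
cz	0.0000
da	4171.0115
db	0.0000
dc	0.0000
dd	347.5843
de	9732.3601
df	0.0000
dg	347.5843
dh	0.0000
di	3823.4272
dj	0.0000
dk	0.0000
dl	347.5843
dm	0.0000
dn	0.0000
do	3823.4272
dp	0.0000
dq	0.0000
dr	2085.5057
ds	347.5843
dt	0.0000
du	4171.0115
dv	0.0000
dw	0.0000
dx	0.0000
dy	1042.7529
dz	0.0000
ea	18421.9673
eb	347.5843
ec	1737.9214
ed	4866.1800
ee	12165.4501
ef	1390.3372
eg	0.0000
eh	0.0000
ei	1042.7529
ej	0.0000
ek	1390.3372
el	7646.8544
em	2433.0900
en	9384.7758
eo	0.0000
ep	2433.0900
eq	0.0000
er	6951.6858
es	5213.7643
et	1390.3372
eu	0.0000
ev	1042.7529
ew	4518.5958
ex	1390.3372
ey	1390.3372
ez	0.0000
fa	4866.1800
fb	0.0000
fc	0.0000
fd	0.0000
fe	4171.0115
ff	347.5843
fg	0.0000
fh	0.0000
fi	3475.8429
fj	0.0000
fk	0.0000
fl	3128.2586
fm	0.0000
fn	0.0000
fo	5561.3486
fp	0.0000
fq	0.0000
fr	1042.7529
fs	0.0000
ft	2433.0900
fu	2433.0900
fv	0.0000
fw	0.0000
fx	0.0000
fy	0.0000
fz	0.0000
ga	3823.4272
gb	0.0000
gc	0.0000
gd	0.0000
ge	3823.4272
gf	0.0000
gg	0.0000
gh	695.1686
gi	1042.7529
gj	0.0000
gk	0.0000
gl	1737.9214
gm	0.0000
gn	347.5843
go	3128.2586
gp	0.0000
gq	0.0000
gr	3128.2586
gs	0.0000
gt	0.0000
gu	1390.3372
gv	0.0000
gw	0.0000
gx	0.0000
gy	0.0000
gz	0.0000
ha	7299.2701
hb	0.0000
hc	0.0000
hd	0.0000
he	8342.0229
hf	0.0000
hg	0.0000
hh	0.0000
hi	5213.7643
hj	0.0000
hk	0.0000
hl	0.0000
hm	0.0000
hn	0.0000
ho	6951.6858
hp	0.0000
hq	0.0000
hr	0.0000
hs	0.0000
ht	0.0000
hu	2433.0900
hv	0.0000
hw	0.0000
hx	0.0000
hy	347.5843
hz	0.0000
ia	1042.7529
ib	695.1686
ic	4866.1800
id	6256.5172
ie	1390.3372
if	1737.9214
ig	1390.3372
ih	0.0000
ii	0.0000
ij	0.0000
ik	1390.3372
il	11817.8658
im	3823.4272
in	14598.5401
io	695.1686
ip	4518.5958
iq	0.0000
ir	5213.7643
is	5561.3486
it	5908.9329
iu	0.0000
iv	1737.9214
iw	0.0000
ix	0.0000
iy	0.0000
iz	695.1686
ja	1042.7529
jb	0.0000
jc	0.0000
jd	0.0000
je	347.5843
jf	0.0000
jg	0.0000
jh	0.0000
ji	0.0000
jj	0.0000
jk	0.0000
jl	0.0000
jm	0.0000
jn	0.0000
jo	695.1686
jp	0.0000
jq	0.0000
jr	0.0000
js	0.0000
jt	0.0000
ju	1390.3372
jv	0.0000
jw	0.0000
jx	0.0000
jy	0.0000
jz	0.0000
ka	347.5843
kb	0.0000
kc	0.0000
kd	0.0000
ke	6951.6858
kf	0.0000
kg	0.0000
kh	0.0000
ki	2433.0900
kj	0.0000
kk	0.0000
kl	0.0000
km	0.0000
kn	2085.5057
ko	0.0000
kp	0.0000
kq	0.0000
kr	0.0000
ks	0.0000
kt	0.0000
ku	0.0000
kv	0.0000
kw	0.0000
kx	0.0000
ky	0.0000
kz	0.0000
la	10079.9444
lb	0.0000
lc	0.0000
ld	4171.0115
le	11470.2815
lf	2085.5057
lg	0.0000
lh	0.0000
li	6604.1015
lj	0.0000
lk	2085.5057
ll	10775.1130
lm	1390.3372
ln	0.0000
lo	8689.6072
lp	695.1686
lq	0.0000
lr	0.0000
ls	347.5843
lt	4171.0115
lu	5561.3486
lv	0.0000
lw	0.0000
lx	0.0000
ly	2085.5057
lz	0.0000
ma	5908.9329
mb	2085.5057
mc	0.0000
md	0.0000
me	9732.3601
mf	0.0000
mg	0.0000
mh	0.0000
mi	3475.8429
mj	0.0000
mk	0.0000
ml	0.0000
mm	0.0000
mn	347.5843
mo	5561.3486
mp	3475.8429
mq	0.0000
mr	0.0000
ms	0.0000
mt	0.0000
mu	2085.5057
mv	0.0000
mw	0.0000
mx	0.0000
my	695.1686
mz	0.0000
na	1390.3372
nb	0.0000
nc	1042.7529
nd	6604.1015
ne	11122.6973
nf	0.0000
ng	4518.5958
nh	0.0000
ni	1737.9214
nj	0.0000
nk	4171.0115
nl	347.5843
nm	0.0000
nn	0.0000
no	3823.4272
np	0.0000
nq	0.0000
nr	0.0000
ns	695.1686
nt	6951.6858
nu	695.1686
nv	347.5843
nw	0.0000
nx	0.0000
ny	1390.3372
nz	0.0000
oa	6604.1015
ob	1042.7529
oc	1737.9214
od	4171.0115
oe	1737.9214
of	1737.9214
og	1042.7529
oh	0.0000
oi	2780.6743
oj	0.0000
ok	2433.0900
ol	10775.1130
om	4866.1800
on	9037.1915
oo	10427.5287
op	4518.5958
oq	0.0000
or	9732.3601
os	5213.7643
ot	4866.1800
ou	4171.0115
ov	2085.5057
ow	5908.9329
ox	0.0000
oy	347.5843
oz	347.5843
pa	6951.6858
pb	0.0000
pc	0.0000
pd	0.0000
pe	6256.5172
pf	0.0000
pg	0.0000
ph	0.0000
pi	3823.4272
pj	0.0000
pk	0.0000
pl	3128.2586
pm	0.0000
pn	0.0000
po	5561.3486
pp	0.0000
pq	0.0000
pr	1042.7529
ps	0.0000
pt	347.5843
pu	2780.6743
pv	0.0000
pw	0.0000
px	0.0000
py	347.5843
pz	0.0000
qa	0.0000
qb	0.0000
qc	0.0000
qd	0.0000
qe	0.0000
qf	0.0000
qg	0.0000
qh	0.0000
qi	0.0000
qj	0.0000
qk	0.0000
ql	0.0000
qm	0.0000
qn	0.0000
qo	0.0000
qp	0.0000
qq	0.0000
qr	0.0000
qs	0.0000
qt	0.0000
qu	695.1686
qv	0.0000
qw	0.0000
qx	0.0000
qy	0.0000
qz	0.0000
ra	9037.1915
rb	1042.7529
rc	0.0000
rd	3475.8429
re	16336.4616
rf	695.1686
rg	347.5843
rh	0.0000
ri	6256.5172
rj	0.0000
rk	2780.6743
rl	1042.7529
rm	3128.2586
rn	4518.5958
ro	8689.6072
rp	347.5843
rq	0.0000
rr	0.0000
rs	0.0000
rt	3128.2586
ru	3823.4272
rv	0.0000
rw	0.0000
rx	0.0000
ry	1390.3372
rz	0.0000
sa	5561.3486
sb	0.0000
sc	1042.7529
sd	0.0000
se	10079.9444
sf	0.0000
sg	0.0000
sh	6951.6858
si	3128.2586
sj	0.0000
sk	2780.6743
sl	3475.8429
sm	347.5843
sn	695.1686
so	6951.6858
sp	2780.6743
sq	0.0000
sr	0.0000
ss	4171.0115
st	14250.9559
su	2085.5057
sv	0.0000
sw	1737.9214
sx	0.0000
sy	695.1686
sz	0.0000
ta	5213.7643
tb	0.0000
tc	0.0000
td	0.0000
te	9732.3601
tf	0.0000
tg	0.0000
th	5561.3486
ti	3823.4272
tj	0.0000
tk	0.0000
tl	0.0000
tm	0.0000
tn	0.0000
to	5908.9329
tp	0.0000
tq	0.0000
tr	2780.6743
ts	695.1686
tt	0.0000
tu	2433.0900
tv	0.0000
tw	695.1686
tx	0.0000
ty	1042.7529
tz	0.0000
ua	347.5843
ub	1737.9214
uc	1737.9214
ud	1042.7529
ue	2085.5057
uf	347.5843
ug	1737.9214
uh	0.0000
ui	1390.3372
uj	0.0000
uk	347.5843
ul	4866.1800
um	3128.2586
un	5908.9329
uo	0.0000
up	1042.7529
uq	0.0000
ur	8342.0229
us	7299.2701
ut	2085.5057
uu	0.0000
uv	0.0000
uw	0.0000
ux	347.5843
uy	0.0000
uz	0.0000
va	1390.3372
vb	0.0000
vc	0.0000
vd	0.0000
ve	10079.9444
vf	0.0000
vg	0.0000
vh	0.0000
vi	2085.5057
vj	0.0000
vk	0.0000
vl	0.0000
vm	0.0000
vn	0.0000
vo	1042.7529
vp	0.0000
vq	0.0000
vr	0.0000
vs	0.0000
vt	0.0000
vu	0.0000
vv	0.0000
vw	0.0000
vx	0.0000
vy	1042.7529
vz	0.0000
wa	6604.1015
wb	0.0000
wc	0.0000
wd	0.0000
we	3128.2586
wf	0.0000
wg	0.0000
wh	1737.9214
wi	5561.3486
wj	0.0000
wk	347.5843
wl	695.1686
wm	0.0000
wn	2780.6743
wo	2780.6743
wp	0.0000
wq	0.0000
wr	695.1686
ws	347.5843
wt	0.0000
wu	0.0000
wv	0.0000
ww	0.0000
wx	0.0000
wy	0.0000
wz	0.0000
xa	347.5843
xb	0.0000
xc	0.0000
xd	0.0000
xe	0.0000
xf	0.0000
xg	0.0000
xh	0.0000
xi	695.1686
xj	0.0000
xk	0.0000
xl	0.0000
xm	0.0000
xn	0.0000
xo	0.0000
xp	0.0000
xq	0.0000
xr	0.0000
xs	0.0000
xt	695.1686
xu	0.0000
xv	0.0000
xw	0.0000
xx	0.0000
xy	0.0000
xz	0.0000
ya	1042.7529
yb	0.0000
yc	0.0000
yd	0.0000
ye	695.1686
yf	0.0000
yg	0.0000
yh	0.0000
yi	0.0000
yj	0.0000
yk	0.0000
yl	0.0000
ym	347.5843
yn	0.0000
yo	1042.7529
yp	347.5843
yq	0.0000
yr	0.0000
ys	347.5843
yt	347.5843
yu	0.0000
yv	0.0000
yw	0.0000
yx	0.0000
yy	0.0000
yz	0.0000
za	0.0000
zb	0.0000
zc	0.0000
zd	0.0000
ze	2780.6743
zf	0.0000
zg	0.0000
zh	0.0000
zi	347.5843
zj	0.0000
zk	0.0000
zl	0.0000
zm	0.0000
zn	0.0000
zo	695.1686
zp	0.0000
zq	0.0000
zr	0.0000
zs	0.0000
zt	0.0000
zu	0.0000
zv	0.0000
zw	0.0000
zx	0.0000
zy	347.5843
zz	347.5843
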