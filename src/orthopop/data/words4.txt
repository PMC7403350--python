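able
ache
acid
aged
ally
also
ante
area
army
aunt
away
axis
baby
back
bail
bait
bake
bald
ball
band
bank
bare
bark
barn
base
bath
bead
beam
bean
bear
beat
beef
been
beer
bell
belt
bend
bent
best
bias
bike
bill
bind
bird
bite
blew
blow
blue
boat
body
boil
bold
bolt
bomb
bond
bone
book
boom
boot
bore
born
boss
both
bowl
brag
brew
brim
brow
bulk
bull
bump
burn
bury
bush
bust
busy
cafe
cage
cake
calf
call
calm
came
camp
cane
cape
card
care
cart
case
cash
cast
cave
cell
cent
chat
chef
chew
chin
chip
chop
cite
city
clan
clap
claw
clay
clip
club
clue
coal
coat
code
coil
coin
cold
colt
comb
come
cone
cook
cool
cope
copy
cord
core
corn
cost
coup
cove
crab
crew
crop
crow
cube
cuff
cult
curb
cure
curl
cute
dame
damp
dare
dark
darn
dart
dash
data
date
dawn
days
dead
deaf
deal
dean
dear
debt
deck
deed
deep
deer
demo
deny
desk
dial
dice
diet
dime
dine
dire
dirt
disc
dish
dive
dock
does
dome
done
doom
door
dose
dove
down
drag
draw
drew
drip
drop
drum
dual
duck
dude
duel
duke
dull
dumb
dump
dune
dusk
dust
duty
each
earl
earn
ease
east
easy
echo
edge
edit
envy
epic
even
ever
evil
exam
exit
face
fact
fade
fail
fair
fake
fall
fame
fang
fare
farm
fast
fate
fear
feat
feed
feel
fees
fell
felt
fern
file
fill
film
find
fine
fire
firm
fish
fist
five
flag
flat
flaw
fled
flee
flew
flip
flow
flux
foam
foil
fold
folk
fond
font
food
fool
foot
ford
fore
fork
form
fort
foul
four
free
frog
from
fuel
full
fume
fund
fury
fuse
fuss
gain
gait
gala
game
gang
gasp
gate
gave
gaze
gear
gene
gift
girl
give
glad
glee
glow
glue
goal
goat
goes
gold
golf
gone
good
gown
grab
gray
grew
grey
grid
grim
grin
grip
grow
gulf
guru
gust
guts
hack
hail
hair
half
hall
halt
hand
hang
hard
hare
harm
harp
hate
haul
have
hawk
haze
head
heal
heap
hear
heat
heed
heel
heir
held
hell
helm
help
herb
herd
here
hero
hide
high
hike
hill
hint
hire
hiss
hive
hold
hole
holy
home
hood
hoof
hook
hope
horn
hose
host
hour
howl
huge
hull
hunt
hurt
hush
hymn
icon
idea
idle
idol
inch
into
iron
item
jade
jail
jazz
jeep
joke
jolt
jump
junk
jury
just
keen
keep
kept
kick
kind
king
kiss
kite
knee
knew
knit
knob
knot
know
lace
lack
lady
laid
lake
lamb
lame
lamp
land
lane
last
late
lava
lawn
lazy
lead
leaf
lean
leap
left
lend
lens
lent
less
liar
lice
lick
life
lift
like
limb
lime
limp
line
link
lion
list
live
load
loaf
loan
lock
loft
logo
lone
long
look
loop
lord
lose
loss
lost
loud
love
luck
lump
lung
lure
lurk
lush
lust
made
maid
mail
main
make
male
mall
malt
many
mare
mark
mask
mass
mast
mate
math
maze
meal
mean
meat
meek
meet
melt
memo
mend
menu
mere
mesh
mess
mild
mile
milk
mill
mind
mine
mint
miss
mist
moan
moat
mock
mode
mold
mole
monk
mood
moon
more
moss
most
moth
move
much
mule
muse
must
mute
myth
nail
name
navy
near
neat
neck
need
nest
news
next
nice
nick
nine
node
none
noon
norm
nose
note
noun
nuts
oath
obey
odds
oily
okay
omit
once
only
onto
ooze
open
oral
oven
over
pace
pack
pact
page
paid
pain
pair
pale
palm
pane
pant
park
part
pass
past
path
pave
pawn
peak
pear
peat
peck
peel
peer
pest
pick
pier
pike
pile
pill
pine
pink
pint
pipe
plan
play
plea
plot
plow
ploy
plug
plum
plus
poem
poet
pole
poll
pond
pony
pool
poor
pope
pork
port
pose
post
pour
pray
prey
prop
pull
pulp
pump
punk
pure
push
quit
quiz
race
rack
raft
rage
raid
rail
rain
rake
ramp
rank
rant
rare
rash
rate
rave
read
real
reap
rear
reed
reef
reel
rely
rent
rest
ribs
rice
rich
ride
rift
ring
riot
ripe
rise
risk
road
roam
roar
robe
rock
rode
role
roll
roof
room
root
rope
rose
ruby
rude
ruin
rule
rung
runs
rush
rust
sack
safe
saga
sage
said
sail
sake
sale
salt
same
sand
sane
sang
sank
save
scan
scar
seal
seam
seat
sect
seed
seek
seem
seen
self
sell
send
sent
sewn
shed
ship
shoe
shop
shot
show
shut
sick
side
sigh
sign
silk
sing
sink
site
size
skew
skin
skip
slab
slam
slap
sled
slid
slim
slip
slot
slow
slug
smug
snap
snow
soak
soap
soar
sock
soda
sofa
soft
soil
sold
sole
solo
some
song
soon
sore
sort
soul
soup
sour
spam
span
spin
spot
spun
spur
stab
star
stay
stem
step
stew
stir
stop
stow
stub
stun
such
suit
sung
sunk
sure
surf
swam
swan
swap
sway
swim
tack
tact
tail
take
tale
talk
tall
tame
tank
tape
task
team
tear
tell
tend
tent
term
test
text
than
that
them
then
they
thin
this
thus
tick
tide
tidy
tier
tile
till
tilt
time
tiny
tire
toad
toil
told
toll
tomb
tone
tool
tore
torn
toss
tour
town
trap
tray
tree
trek
trim
trip
trot
true
tube
tuck
tune
turf
turn
twig
twin
type
ugly
undo
unit
upon
urge
used
user
vain
vase
vast
veal
veer
veil
vein
vent
verb
very
vest
veto
vibe
vice
view
vine
visa
void
volt
vote
wage
wait
wake
walk
wall
want
ward
warm
warn
wart
wash
wasp
wave
wavy
weak
wear
weed
week
weep
well
went
were
west
what
when
whim
whip
whom
wide
wife
wild
will
wind
wine
wing
wink
wipe
wire
wise
wish
with
wolf
wood
wool
word
wore
work
worm
worn
wrap
wren
yard
yarn
yawn
year
yell
yoga
yoke
your
zeal
zero
zest
zinc
zone
zoom
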