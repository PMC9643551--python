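a
about
again
all
am
are
arm
back
bed
better
break
bring
call
can
close
cold
comfortable
coming
day
did
dinner
do
doctor
doing
door
down
dry
faith
family
favorite
feel
feeling
fine
food
for
glad
glasses
go
good
great
hard
head
help
here
hope
hot
how
hungry
hurts
i
in
invention
is
it
kind
later
leave
leg
let
light
like
listen
love
me
morning
mouth
move
much
music
my
name
need
nice
night
no
not
nurse
of
off
on
open
outside
pain
please
quiet
ready
rest
right
said
see
sick
sleep
slept
some
take
tell
thank
that
the
thing
thirsty
this
time
tired
to
today
tomorrow
too
try
turn
tv
up
us
very
want
was
watch
water
we
weather
well
what
when
where
will
window
work
worry
would
wrong
yes
yet
you
your
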