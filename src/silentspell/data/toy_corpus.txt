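i am thirsty
i am hungry
i am tired
i am cold
i am hot
i am fine
i am in pain
i am not in pain
i need water
i need food
i need help
i need my glasses
i need my nurse
i need to rest
i need to sleep
i would like some water
i would like some food
i would like to rest
i would like to go outside
i would like to watch tv
please bring me my glasses
please bring me some water
please bring me some food
please call my family
please call the nurse
please call the doctor
please turn on the light
please turn off the light
please turn on the tv
please turn off the tv
please open the window
please close the window
please move my bed up
please move my bed down
can you help me
can you call my family
can you bring me water
can you turn on the light
can you close the door
can you open the door
how are you today
how are you feeling
how is the weather today
how was your day
what time is it
what day is it
what is for dinner
what is your name
where is my family
where is the nurse
thank you very much
thank you for your help
that is very kind of you
that is not what i said
that is right
that is wrong
yes please
no thank you
i love you
i am glad to see you
it is good to see you
good morning to you
good night
see you later
see you tomorrow
my head hurts
my back hurts
my arm hurts
my leg hurts
my mouth is dry
it hurts here
it is too cold in here
it is too hot in here
it is very nice outside
the weather is nice today
do not do that again
do not worry about me
do not leave yet
you are very kind
you are doing great
are you comfortable
are you ready
is my family here
is the doctor coming today
when is the doctor coming
when is my family coming
when can i go outside
i want to go outside
i want to watch tv
i want to listen to music
i like music
i like the quiet
i do not like this
i do not want that
i feel much better today
i feel sick
i did not sleep well
i slept very well
this is hard work
this is my favorite
we can try again later
we did well today
let us try again
let us take a break
i need a break
faith is a fine invention
hope is a good thing
time will tell
all is well
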