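name,weight,calorie
apple juice,180.5,N/a
almond milk,175.5,41.57
banana,143.6,127.80
banana milk,174.6,110.27
chocolate bar (high protein),35,167.00
beef steak,68.1,319.39
beef steak with source,79,330.29
black noodles,127.4,170.00
black noodles with oil,132.4,N/a
blacktea,168,52.68
bread,47.8,129.54
bread and butter,54.8,182.04
castella,89.9,287.68
cherryade,168,79.06
chicken breast,100.6,109.00
chicken noodles,70,255.00
black chocolate,40.37,222.04
milk chocolate,41,228.43
chocolate milk,180.1,122.62
cider,166,70.55
clam chowder,160,90.00
coffee,167,18.56
coffee with sugar (10%),167,55.74
coffee with sugar (20%),167,92.92
coffee with sugar (30%),167,130.11
coke,166,76.36
corn milk,166.6,97.18
corn soup,160,85.00
cup noodle,262.5,120.00
rice with tuna and pepper,305,418.15
dietcoke,166,0.00
choclate bar,50,249.00
roasted duck,117.2,360.98
orange soda,173.6,33.33
orange soda (sugar-free),166.2,2.77
fried potato and powder,120,364.92
sports drink,177.1,47.23
ginger tea,178.3,96.79
honey tea,183.9,126.69
caffelatte,171.6,79.13
caffelatte with sugar (10%),171.6,115.66
caffelatte with sugar (20%),171.6,152.19
caffelatte with sugar (30%),171.6,188.72
mango candy,36.4,91.00
mango jelly,58.6,212.43
milk,171,94.50
sweet milk,171,N/a
green soda,174.5,84.55
pizza (seafood),60,148.83
pizza (combination),70.9,175.87
sports drink (white),175.8,43.95
pork (steamed),119.3,441.41
potato chips,23.5,130.82
potato chips (onion flavor),23.5,133.95
sports drink (blue),170,17.00
chocolate bar (with fruits),40,170.00
milk pudding,140,189.41
ramen (Korean-style noodles),308,280.00
rice (steamed),172.3,258.45
rice cake,119.3,262.46
rice cake and honey,127.9,288.60
rice juice,173.8,106.21
"rice (steamed, low-calorie)",164.6,171.18
multi-grain rice,175.3,258.08
rice noodles,278,140.00
cracker,41.5,217.88
salad1 (lettuce and cucumber),96.8,24.20
salad1 with olive oil,106,37.69
salad2 (cabbage and carrot),69.1,17.28
salad2 with fruit-dressing,79,28.04
armond cereal (served with milk),191.7,217.36
corn cereal (served with milk),192,205.19
soybean milk,171.9,85.95
spagetti,250,373.73
kiwi soda (sugar-free),166,2.34
tofu,138.6,62.37
cherry tomato,200,36.00
tomato juice,176.8,59.80
cherry tomato and syrup,210,61.90
fruit soda,169,27.04
vinegar,168,20.16
pure water,166,0.00
watermelon juice,177.7,79.97
grape soda,170.9,92.43
grape soda (sugar-free),170.9,0.00
fried potato,110.5,331.50
yogurt,179,114.56
yogurt and sugar,144.6,106.04
milk soda,167,86.84
salt crackers,41.3,218.89
onion soap,160,83.00
orange juice,182.6,82.17
peach (cutted),142,55.38
pear juice,181.5,90.02
peach and syrup,192,124.80
peanuts,37.1,217.96
peanuts and salt,37.3,218.21
milk tea,167,63.46
pizza (beef),85.5,212.08
pizza (potato),72.3,179.34
plain yogurt,143.7,109.89
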