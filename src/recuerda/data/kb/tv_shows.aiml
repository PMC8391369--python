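<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="tv_shows" description="programas de televisión favoritos">
    <category role="trigger">
      <pattern>TELEVISIÓN</pattern>
      <template><random>
        <li>¿Es cierto que tu programa favorito es <get name="programa_favorito"/>?</li>
        <li>¿Qué programa de televisión esperabas con ganas cada semana?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ TELEVISIÓN</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>TELEVISIÓN _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ TELEVISIÓN _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>PROGRAMA</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PROGRAMA</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>PROGRAMA _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PROGRAMA _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>PROGRAMAS</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PROGRAMAS</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>PROGRAMAS _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PROGRAMAS _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>TELE</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ TELE</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>TELE _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ TELE _</pattern>
      <template><srai>TELEVISIÓN</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Me encantaría verlo contigo! ¿Qué te gusta de <get name="programa_favorito"/>?</li>
        <li>¿A qué hora solías ver <get name="programa_favorito"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Está bien. ¿Qué programa te hacía reír?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>La televisión trae buenos momentos. ¿Qué programa recuerdas?</li>
        <li>Ver la tele acompaña mucho. ¿Qué programas veías en familia?</li>
      </random></template>
    </category>
  </topic>
</aiml>
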